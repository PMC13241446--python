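"""Project the kinetics onto a synthetic frontal-impact strain field.

Generates a hexahedral grid with a focal high-strain Gaussian blob
(emulating the maximum-principal-strain pattern of a frontal head
impact), normalizes it, and builds the spatiotemporal tau map.  The
node-mean of every map equals the homogeneous curve X(t) by
construction of the correction factor S(t); the strain decides which
nodes carry the burden.
"""

import numpy as np

from tauavrami import (
    AmplitudeFactor,
    KineticParameters,
    SyntheticFieldSpec,
    generate_synthetic_field,
    normalize_field,
    tau_map,
    transformed_fraction,
)

field, _ = generate_synthetic_field(
    SyntheticFieldSpec(seed=1, dims=(15, 15, 15), noise_sd=0.01)
)
w = normalize_field(field)
params = KineticParameters(v0=0.05, J0=1e-5, kv=0.01, kJ=0.005)
series = tau_map(w, AmplitudeFactor(), params)

print("day    S(t)        mean tau    X(t)        max tau")
for j, t in enumerate(series.times):
    x = transformed_fraction(t, params)
    print(
        f"{t:>5.0f}  {series.s_factors[j]:<10.4g} "
        f"{series.spatial_mean()[j]:<11.6f} {x:<11.6f} {series.tau[:, j].max():.6f}"
    )

dev = np.max(np.abs(series.spatial_mean()
                    - [transformed_fraction(t, params) for t in series.times]))
print(f"\nmax |mean tau - X|: {dev:.2e}  (mean enforcement)")
print("high-strain nodes reach tau far above the 0.35 global mean bound;")
print("low-strain nodes stay near zero - mechanics set the spatial pattern.")
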