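"""Built-in reference data: the murine calibration series and published fit.

The calibration dataset is a four-point global AT8-positive tau burden
series from tau-transgenic mice given a single controlled cortical
impact: mean AT% across cortex, hippocampus and brainstem at 1, 7, 60
and 180 days post-injury.  These numbers are the model's only biological
anchor; everything temporal is calibrated against them.
"""

from __future__ import annotations

import pandas as pd

from .calibration import ObservationSeries
from .kinetics import KineticParameters

__all__ = [
    "murine_tau_observations",
    "published_parameters",
    "published_prediction_table",
]


def murine_tau_observations() -> ObservationSeries:
    """Four-point murine CCI tau-burden series (days, AT%-units)."""
    return ObservationSeries(times=(1.0, 7.0, 60.0, 180.0), tau=(0.0032, 0.0048, 0.0085, 0.2533))


def published_parameters() -> KineticParameters:
    """Kinetic parameters as printed in the original calibration report.

    Caveat: plugged straight into the closed-form kinetics with t in
    days these values give X(1) ~ 4e-10, far below the reported predicted
    tau at day 1 (0.00388) — the printed quadruple is not reproducible
    within the stated equations (an unstated unit conversion or
    transformed fitting variable is likely).  They are exposed for
    reference; use :func:`tauavrami.calibration.calibrate` for a
    parameter set that actually fits the observations.
    """
    return KineticParameters(v0=0.0472197, J0=1.12609e-5, kv=2.89573e-6, kJ=3.14002e-6)


def published_prediction_table() -> pd.DataFrame:
    """Observed and published model-predicted tau at the calibration times."""
    return pd.DataFrame(
        {
            "time_days": [1.0, 7.0, 60.0, 180.0],
            "tau_observed": [0.0032, 0.0048, 0.0085, 0.2533],
            "tau_predicted": [0.00388, 0.00448, 0.00794, 0.25376],
        }
    )
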