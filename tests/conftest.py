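import numpy as np
import pytest

from tauavrami import (
    AmplitudeFactor,
    KineticParameters,
    ObservationSeries,
    SyntheticFieldSpec,
    generate_synthetic_field,
    murine_tau_observations,
    normalize_field,
    trajectory,
)


@pytest.fixture(scope="session")
def murine_obs() -> ObservationSeries:
    return murine_tau_observations()


@pytest.fixture(scope="session")
def baseline_params() -> KineticParameters:
    """Sensitivity-analysis baseline: all four parameters at 1e-3."""
    return KineticParameters(v0=1e-3, J0=1e-3, kv=1e-3, kJ=1e-3)


@pytest.fixture(scope="session")
def saturating_params() -> KineticParameters:
    """Parameters whose trajectory sweeps the full sigmoid within ~150 days."""
    return KineticParameters(v0=0.05, J0=1e-5, kv=0.01, kJ=0.005)


@pytest.fixture(scope="session")
def recovery_series(saturating_params) -> tuple[ObservationSeries, KineticParameters]:
    """Noise-free synthetic observations over the pre-saturation window."""
    times = [1.0] + [12.0 * i for i in range(1, 13)]
    traj = trajectory(times, saturating_params)
    return ObservationSeries(times, traj.x), saturating_params


@pytest.fixture(scope="session")
def focal_field():
    """Small focal (frontal-blob) synthetic field with mesh connectivity."""
    spec = SyntheticFieldSpec(seed=3, dims=(12, 12, 12), noise_sd=0.01)
    return generate_synthetic_field(spec)


@pytest.fixture(scope="session")
def focal_normalized(focal_field):
    return normalize_field(focal_field[0])


@pytest.fixture(scope="session")
def unit_amp() -> AmplitudeFactor:
    return AmplitudeFactor()
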