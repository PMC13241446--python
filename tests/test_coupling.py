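"""Tests of the strain-field projection and mean-enforcing correction."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tauavrami import (
    AmplitudeFactor,
    InfeasibleMeanError,
    InvalidArgumentError,
    KineticParameters,
    MechanicalField,
    NormalizedField,
    SaturationBound,
    local_extended,
    normalize_field,
    solve_correction,
    tau_map,
    transformed_fraction,
)

#: Frozen: root of (1/2)[(1-e^{-S}) + (1-e^{-S/16})] = 0.35(1-e^{-1}).
TWO_NODE_S = 0.5277021700196151
#: Frozen: -ln(1 - 0.35(1 - e^{-1})).
ONE_CLASS_S = 0.2500551872163993


def make_norm(w):
    w = np.asarray(w, dtype=float)
    return NormalizedField(
        node_ids=np.arange(w.size), w=w, w0_min=0.0, w0_max=1.0
    )


class TestNormalizeField:
    def test_direct_example(self):
        f = MechanicalField(node_ids=np.arange(3), w0=np.array([2.0, 4.0, 6.0]))
        w = normalize_field(f)
        assert w.w.tolist() == [0.0, 0.5, 1.0]
        assert (w.w0_min, w.w0_max) == (2.0, 6.0)

    def test_constant_field_convention(self):
        f = MechanicalField(node_ids=np.arange(3), w0=np.full(3, 5.0))
        assert normalize_field(f).w.tolist() == [1.0, 1.0, 1.0]

    def test_affine_invariance(self):
        rng = np.random.default_rng(0)
        w0 = rng.uniform(0, 2, 50)
        f1 = MechanicalField(node_ids=np.arange(50), w0=w0)
        f2 = MechanicalField(node_ids=np.arange(50), w0=3.5 * w0 + 11.0)
        assert np.allclose(normalize_field(f1).w, normalize_field(f2).w, atol=1e-12)

    def test_nonfinite_rejected_with_node_list(self):
        with pytest.raises(InvalidArgumentError, match=r"\b7\b"):
            MechanicalField(node_ids=np.array([5, 7]), w0=np.array([1.0, np.nan]))

    def test_duplicate_node_ids_rejected(self):
        with pytest.raises(InvalidArgumentError):
            MechanicalField(node_ids=np.array([1, 1]), w0=np.array([0.0, 1.0]))


class TestLocalExtended:
    def test_unit_weight_passthrough(self):
        w = make_norm([1.0])
        assert local_extended(w, AmplitudeFactor(), ye=2.5)[0] == 2.5

    def test_fourth_power_weighting(self):
        w = make_norm([0.5])
        assert local_extended(w, AmplitudeFactor(), ye=16.0)[0] == pytest.approx(1.0)

    def test_amplitude_fourth_power(self):
        w = make_norm([1.0])
        amp = AmplitudeFactor(Q=2.0)
        assert local_extended(w, amp, ye=1.0)[0] == pytest.approx(16.0)

    def test_contrast_ratio_exact(self):
        w = make_norm([0.9, 0.3])
        y = local_extended(w, AmplitudeFactor(), ye=5.0)
        assert y[0] / y[1] == pytest.approx((0.9 / 0.3) ** 4, rel=1e-12)

    def test_amplitude_validation(self):
        with pytest.raises(InvalidArgumentError):
            AmplitudeFactor(Q=-1.0)


class TestSolveCorrection:
    def test_one_class_closed_form(self):
        s = solve_correction(make_norm([1.0, 1.0, 1.0]), ye=1.0)
        assert s == pytest.approx(ONE_CLASS_S, abs=1e-10)

    def test_two_node_value(self):
        s = solve_correction(make_norm([1.0, 0.5]), ye=1.0)
        assert s == pytest.approx(TWO_NODE_S, abs=1e-8)

    def test_vacuous_at_zero_extended_volume(self):
        assert solve_correction(make_norm([1.0, 0.2]), ye=0.0) == 1.0

    def test_infeasible_when_too_few_positive_nodes(self):
        # 1 positive node of 10 -> mean saturates at 0.1 < X for large ye
        w = make_norm([1.0] + [0.0] * 9)
        with pytest.raises(InfeasibleMeanError) as exc:
            solve_correction(w, ye=50.0)
        assert exc.value.positive_fraction == pytest.approx(0.1)

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(
        n=st.integers(2, 60),
        seed=st.integers(0, 2**31 - 1),
        ye=st.floats(1e-6, 50.0),
    )
    def test_mean_enforced_for_random_fields(self, n, seed, ye):
        rng = np.random.default_rng(seed)
        w = make_norm(rng.uniform(0.05, 1.0, n))
        s = solve_correction(w, ye=ye, tol=1e-12)
        mean = np.mean(-np.expm1(-s * w.w**4 * ye))
        target = 0.35 * -math.expm1(-ye)
        assert abs(mean - target) <= 1e-10


class TestTauMap:
    def test_single_node_equals_homogeneous_curve(self, saturating_params):
        w = make_norm([0.63])
        grid = [1.0, 50.0, 100.0, 150.0]
        series = tau_map(w, AmplitudeFactor(), saturating_params, grid=grid)
        want = [transformed_fraction(t, saturating_params) for t in grid]
        assert np.allclose(series.tau[0], want, atol=1e-10)

    def test_uniform_field_reduces_to_homogeneous(self, saturating_params):
        w = make_norm(np.ones(40))
        grid = [1.0, 75.0, 150.0]
        series = tau_map(w, AmplitudeFactor(), saturating_params, grid=grid)
        for j, t in enumerate(grid):
            x = transformed_fraction(t, saturating_params)
            assert np.allclose(series.tau[:, j], x, atol=1e-10)
        # S < 1 whenever Y_e > 0: the alpha-saturated target needs damping
        assert np.all(series.s_factors[series.times > 0] < 1.0)

    def test_mean_enforcement_and_ordering(self, focal_normalized, saturating_params):
        series = tau_map(focal_normalized, AmplitudeFactor(), saturating_params)
        want = np.array(
            [transformed_fraction(t, saturating_params) for t in series.times]
        )
        assert np.max(np.abs(series.spatial_mean() - want)) <= 1e-10
        # tau ordering follows w ordering at every time
        order = np.argsort(focal_normalized.w)
        for j in range(series.times.size):
            assert np.all(np.diff(series.tau[order, j]) >= -1e-12)
        # non-decreasing in time per node
        assert np.all(np.diff(series.tau, axis=1) >= -1e-9)
        # local tau stays below the dimensionless bound 1
        assert np.all(series.tau < 1.0)

    def test_mean_enforcement_large_random_field(self, saturating_params):
        rng = np.random.default_rng(42)
        w = make_norm(rng.uniform(0.0, 1.0, 100_000))
        series = tau_map(w, AmplitudeFactor(), saturating_params, grid=[100.0, 150.0])
        want = [transformed_fraction(t, saturating_params) for t in (100.0, 150.0)]
        assert np.max(np.abs(series.spatial_mean() - np.asarray(want))) <= 1e-10

    def test_amplitude_equivalent_to_weight_rescaling(self, saturating_params):
        rng = np.random.default_rng(5)
        w_raw = rng.uniform(0.1, 1.0, 30)
        grid = [60.0, 120.0]
        a = tau_map(make_norm(w_raw), AmplitudeFactor(Q=2.0), saturating_params, grid=grid)
        b = tau_map(make_norm(2.0 * w_raw), AmplitudeFactor(), saturating_params, grid=grid)
        assert np.allclose(a.tau, b.tau, atol=1e-12)
        assert np.allclose(a.s_factors, b.s_factors, atol=1e-12)

    def test_infeasibility_reports_time(self):
        w = make_norm([1.0] + [0.0] * 9)
        p = KineticParameters(v0=0.05, J0=1e-5, kv=0.01, kJ=0.005)
        with pytest.raises(InfeasibleMeanError) as exc:
            tau_map(w, AmplitudeFactor(), p, grid=[1.0, 150.0])
        assert exc.value.time == 150.0

    def test_long_frame_shape(self, saturating_params):
        w = make_norm([0.2, 0.9])
        series = tau_map(w, AmplitudeFactor(), saturating_params, grid=[1.0, 50.0])
        df = series.to_frame()
        assert list(df.columns) == ["node_id", "time_days", "tau"]
        assert len(df) == 4
        assert list(series.s_table().columns) == ["time_days", "s_factor"]
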