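"""Unit and property tests of the homogeneous Avrami kinetics."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tauavrami import (
    InvalidArgumentError,
    KineticParameters,
    KineticsOverflowError,
    PerturbationPlan,
    SaturationBound,
    TimeGrid,
    domain_radius,
    domain_volume,
    extended_volume,
    extended_volume_quadrature,
    growth_velocity,
    nucleation_rate,
    ofat_scan,
    trajectory,
    transformed_fraction,
)
from tauavrami.kinetics import ofat_table


def params(v0=1.0, J0=1.0, kv=0.0, kJ=0.0):
    return KineticParameters(v0=v0, J0=J0, kv=kv, kJ=kJ)


class TestElementaryRates:
    @pytest.mark.parametrize(
        "tp, p, expected",
        [
            (0.0, params(J0=7.0, kJ=0.3), 7.0),  # exp(0) = 1
            (100.0, params(J0=5.0, kJ=0.0), 5.0),  # kJ=0: constant nucleation
            (10.0, params(J0=2.0, kJ=0.1), 2.0 * math.e),
        ],
    )
    def test_nucleation_rate(self, tp, p, expected):
        assert nucleation_rate(tp, p) == pytest.approx(expected, rel=1e-12)

    @pytest.mark.parametrize(
        "t, p, expected",
        [
            (0.0, params(v0=3.0, kv=0.2), 3.0),
            (50.0, params(v0=3.0, kv=0.0), 3.0),  # kv=0: constant growth
            (2.0, params(v0=1.0, kv=-0.5), math.exp(-1.0)),
        ],
    )
    def test_growth_velocity(self, t, p, expected):
        assert growth_velocity(t, p) == pytest.approx(expected, rel=1e-12)

    def test_rates_reject_bad_input(self):
        p = params()
        with pytest.raises(InvalidArgumentError):
            nucleation_rate(float("nan"), p)
        with pytest.raises(InvalidArgumentError):
            growth_velocity(-1.0, p)

    def test_parameter_invariants(self):
        with pytest.raises(InvalidArgumentError):
            KineticParameters(v0=0.0, J0=1.0, kv=0.0, kJ=0.0)
        with pytest.raises(InvalidArgumentError):
            KineticParameters(v0=1.0, J0=-1.0, kv=0.0, kJ=0.0)
        # negative modulation coefficients are meaningful regimes
        KineticParameters(v0=1.0, J0=1.0, kv=-0.5, kJ=-0.5)


class TestDomainGeometry:
    def test_radius_zero_at_birth(self):
        assert domain_radius(3.0, 3.0, params(kv=0.7)) == 0.0

    def test_radius_constant_velocity_limit(self):
        assert domain_radius(4.0, 1.0, params(v0=2.0, kv=0.0)) == pytest.approx(6.0)

    def test_radius_exponential_growth(self):
        # v0=1, kv=ln 2, tp=0, t=1 -> (1/ln2)(2 - 1)
        p = params(v0=1.0, kv=math.log(2.0))
        assert domain_radius(1.0, 0.0, p) == pytest.approx(1.0 / math.log(2.0), rel=1e-12)

    def test_radius_matches_velocity_quadrature(self):
        from scipy.integrate import quad

        p = params(v0=0.7, kv=-0.13)
        want, _ = quad(lambda s: growth_velocity(s, p), 0.5, 9.0)
        assert domain_radius(9.0, 0.5, p) == pytest.approx(want, rel=1e-10)

    def test_radius_rejects_reversed_times(self):
        with pytest.raises(InvalidArgumentError):
            domain_radius(1.0, 2.0, params())

    @pytest.mark.parametrize(
        "t, tp, p, expected",
        [
            (5.0, 5.0, params(), 0.0),
            (1.0, 0.0, params(v0=1.0, kv=0.0), 4.0 * math.pi / 3.0),  # unit sphere
            (2.0, 0.0, params(v0=1.0, kv=0.0), 4.0 * math.pi / 3.0 * 8.0),
        ],
    )
    def test_volume(self, t, tp, p, expected):
        assert domain_volume(t, tp, p) == pytest.approx(expected, rel=1e-12)


class TestExtendedVolume:
    def test_zero_at_time_zero(self):
        assert extended_volume(0.0, params(kv=0.1, kJ=0.1)) == 0.0
        assert extended_volume_quadrature(0.0, params()) == 0.0

    def test_constant_rate_quadrature(self):
        # J=1, v=1 constant: (4 pi/3) int (1-t')^3 dt' = pi/3
        val = extended_volume_quadrature(1.0, params(kv=0.0, kJ=0.0))
        assert val == pytest.approx(math.pi / 3.0, rel=1e-10)

    def test_degenerate_closed_form_hits_constant_rate(self):
        p = params(kv=1e-12, kJ=1e-12)
        assert extended_volume(1.0, p) == pytest.approx(math.pi / 3.0, rel=1e-8)

    def test_constant_rate_asymptote(self):
        # kv, kJ -> 0: Y_e -> (pi/3) J0 v0^3 t^4
        p = KineticParameters(v0=2e-3, J0=5e-4, kv=1e-9, kJ=-1e-9)
        for t in (1.0, 10.0, 100.0):
            want = math.pi / 3.0 * p.J0 * p.v0**3 * t**4
            assert extended_volume(t, p) == pytest.approx(want, rel=1e-6)

    def test_oracle_equivalence_random_draws(self):
        """Closed form vs adaptive quadrature over 200 random parameter draws."""
        rng = np.random.default_rng(20260926)
        worst = 0.0
        for _ in range(200):
            p = KineticParameters(
                v0=10 ** rng.uniform(-6, -1),
                J0=10 ** rng.uniform(-6, -1),
                kv=rng.uniform(-0.05, 0.05),
                kJ=rng.uniform(-0.05, 0.05),
            )
            for t in (1.0, 10.0, 100.0):
                c = extended_volume(t, p)
                q = extended_volume_quadrature(t, p)
                rel = abs(c - q) / max(q, 1e-30)
                worst = max(worst, rel)
        assert worst <= 1e-6

    def test_continuity_across_degeneracy_switch(self):
        # values just above/below the switchover tolerance agree
        t, kJ = 1.0, 0.01
        lo = extended_volume(t, params(kv=0.9999e-6, kJ=kJ))
        hi = extended_volume(t, params(kv=1.0001e-6, kJ=kJ))
        assert lo == pytest.approx(hi, rel=1e-6)

    def test_overflow_guard(self):
        with pytest.raises(KineticsOverflowError) as exc:
            extended_volume(100.0, params(kv=8.0, kJ=8.0))
        assert exc.value.exponent > 700

    def test_negative_time_rejected(self):
        with pytest.raises(InvalidArgumentError):
            extended_volume(-1.0, params())


class TestTransformedFraction:
    def test_zero_extended_volume(self):
        assert transformed_fraction(0.0, params()) == 0.0

    def test_direct_value(self):
        # Y_e = pi/3 at t=1 for unit constant rates
        want = 0.35 * (1.0 - math.exp(-math.pi / 3.0))
        assert transformed_fraction(1.0, params(kv=0.0, kJ=0.0)) == pytest.approx(want)

    def test_saturates_at_alpha(self):
        # huge Y_e: plateau is exactly alpha in double precision
        p = params(v0=10.0, J0=10.0)
        assert transformed_fraction(50.0, p) == 0.35
        assert transformed_fraction(50.0, p, SaturationBound(0.12)) == 0.12

    def test_below_alpha_for_moderate_times(self, baseline_params):
        for t in (1.0, 100.0, 365.0):
            assert transformed_fraction(t, baseline_params) < 0.35

    def test_saturation_bound_validation(self):
        with pytest.raises(InvalidArgumentError):
            SaturationBound(0.0)
        with pytest.raises(InvalidArgumentError):
            SaturationBound(1.5)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(
        v0=st.floats(1e-5, 1e-1),
        J0=st.floats(1e-5, 1e-1),
        kv=st.floats(-0.05, 0.05),
        kJ=st.floats(-0.05, 0.05),
        factor=st.floats(1.0, 3.0),
    )
    def test_monotone_in_each_parameter(self, v0, J0, kv, kJ, factor):
        """X(t) is non-decreasing in v0, J0, kv and kJ separately."""
        base = KineticParameters(v0=v0, J0=J0, kv=kv, kJ=kJ)
        t = 20.0
        x0 = transformed_fraction(t, base)
        for name in ("v0", "J0", "kv", "kJ"):
            kw = {"v0": v0, "J0": J0, "kv": kv, "kJ": kJ}
            kw[name] = kw[name] * factor if name in ("v0", "J0") else kw[name] + (factor - 1.0) * 0.01
            x1 = transformed_fraction(t, KineticParameters(**kw))
            assert x1 >= x0 - 1e-15


class TestTrajectory:
    def test_single_point_grid(self, baseline_params):
        traj = trajectory([0.0], baseline_params)
        assert traj.ye.tolist() == [0.0]
        assert traj.x.tolist() == [0.0]

    def test_matches_pointwise_calls(self, baseline_params):
        grid = TimeGrid([1.0, 7.0, 60.0, 180.0, 365.0])
        traj = trajectory(grid, baseline_params)
        for t, ye, x in zip(grid.times, traj.ye, traj.x):
            assert ye == extended_volume(t, baseline_params)
            assert x == pytest.approx(transformed_fraction(t, baseline_params), abs=1e-18)

    def test_invariants(self, baseline_params):
        traj = trajectory(np.linspace(0.0, 365.0, 74), baseline_params)
        assert np.all(traj.ye >= 0)
        assert np.all(np.diff(traj.ye) >= 0)
        assert np.all(np.diff(traj.x) >= 0)
        assert np.all(traj.x < 0.35)

    def test_grid_validation(self):
        with pytest.raises(InvalidArgumentError):
            TimeGrid([1.0, 1.0])
        with pytest.raises(InvalidArgumentError):
            TimeGrid([-1.0, 2.0])


class TestOFATScan:
    def test_factor_one_rows_identical(self, baseline_params):
        plan = PerturbationPlan(baseline=baseline_params, factors=(1.0,))
        scan = ofat_scan(plan, [1.0, 100.0, 365.0])
        trajs = list(scan.values())
        assert len(trajs) == 4
        for traj in trajs[1:]:
            assert np.array_equal(traj.x, trajs[0].x)

    def test_monotone_in_factor(self, baseline_params):
        """Raising any parameter's factor raises the whole curve."""
        grid = [1.0, 50.0, 100.0, 200.0, 365.0]
        scan = ofat_scan(PerturbationPlan(baseline=baseline_params), grid)
        for target in ("v0", "J0", "kv", "kJ"):
            prev = None
            for f in (0.5, 0.8, 1.0, 1.2, 1.5):
                x = scan[(target, f)].x
                if prev is not None:
                    assert np.all(x >= prev - 1e-15)
                prev = x

    def test_upscaled_v0_strictly_above_baseline(self, baseline_params):
        scan = ofat_scan(PerturbationPlan(baseline=baseline_params), [100.0])
        assert scan[("v0", 1.5)].x[0] > scan[("v0", 1.0)].x[0]

    def test_downscaled_j0_below_baseline(self, baseline_params):
        grid = np.linspace(1.0, 365.0, 40)
        scan = ofat_scan(PerturbationPlan(baseline=baseline_params), grid)
        assert np.all(scan[("J0", 0.5)].x <= scan[("J0", 1.0)].x)

    def test_table_shape(self, baseline_params):
        scan = ofat_scan(PerturbationPlan(baseline=baseline_params), [1.0, 2.0])
        df = ofat_table(scan)
        assert set(df.columns) == {"parameter", "factor", "time_days", "ye", "x"}
        assert len(df) == 4 * 5 * 2
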