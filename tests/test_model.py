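"""The repair function, its derivative, linearization and the theta grid fit."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import integrate, stats

from repairkinetics import (
    InfeasibleThetaError,
    KJMAParams,
    RepairTimeCourse,
    UnfittableRegionError,
    filter_params,
    fit,
    fit_given_theta,
    fit_many,
    linearize,
    pool_time_courses,
    repair_fraction,
    repair_rate,
)
from conftest import noiseless_course


class TestRepairFraction:
    @pytest.mark.parametrize("m,tau,theta", [(1, 60, 1), (2.5, 40, 0.7)])
    def test_zero_at_origin(self, m, tau, theta):
        assert repair_fraction(KJMAParams(m=m, tau=tau, theta=theta), 0) == 0.0

    @pytest.mark.parametrize(
        "m,tau,theta,t,expected",
        [
            (1, 60, 1.0, 60, 1 - math.exp(-1)),       # t = tau closed form
            (2, 60, 0.8, 120, 0.8 * (1 - math.exp(-4))),
        ],
    )
    def test_closed_form_values(self, m, tau, theta, t, expected):
        got = repair_fraction(KJMAParams(m=m, tau=tau, theta=theta), t)
        assert got == pytest.approx(expected, rel=1e-12)

    def test_matches_weibull_cdf(self):
        """f(t)/theta is exactly the Weibull(shape m, scale tau) CDF."""
        ts = np.linspace(0, 400, 101)
        worst = 0.0
        for m in (0.6, 1.0, 1.7, 3.2):
            for tau in (25.0, 60.0, 150.0):
                p = KJMAParams(m=m, tau=tau, theta=0.83)
                ours = repair_fraction(p, ts) / p.theta
                ref = stats.weibull_min.cdf(ts, m, scale=tau)
                worst = max(worst, np.abs(ours - ref).max())
        assert worst <= 1e-12

    def test_monotone_and_bounded(self):
        p = KJMAParams(m=1.8, tau=50, theta=0.75)
        f = repair_fraction(p, np.linspace(0, 600, 2000))
        assert np.all(np.diff(f) >= 0)
        assert f[0] == 0.0 and f[-1] <= p.theta

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            repair_fraction(KJMAParams(m=1, tau=60, theta=1), -1)


class TestRepairRate:
    def test_limit_at_zero_m_equal_one(self):
        p = KJMAParams(m=1, tau=60, theta=0.8)
        assert repair_rate(p, 0) == pytest.approx(0.8 / 60)

    def test_limit_at_zero_m_above_one(self):
        assert repair_rate(KJMAParams(m=2, tau=60, theta=0.8), 0) == 0.0
        assert repair_rate(KJMAParams(m=2, tau=60, theta=0.8), 1e-9) < 1e-10

    def test_divergent_at_zero_for_sublinear_m(self):
        with pytest.raises(ValueError):
            repair_rate(KJMAParams(m=0.7, tau=60, theta=0.8), 0)

    @pytest.mark.parametrize("m,tau,theta,t", [
        (2, 60, 0.8, 60), (0.9, 40, 0.6, 15), (3.5, 100, 1.0, 130),
    ])
    def test_central_difference_oracle(self, m, tau, theta, t):
        p = KJMAParams(m=m, tau=tau, theta=theta)
        h = 1e-5 * t
        numeric = (repair_fraction(p, t + h) - repair_fraction(p, t - h)) / (2 * h)
        assert repair_rate(p, t) == pytest.approx(numeric, rel=1e-6)

    def test_integrates_to_theta(self):
        for m, tau, theta in [(0.8, 30, 0.55), (2, 60, 0.8), (4, 150, 1.0)]:
            p = KJMAParams(m=m, tau=tau, theta=theta)
            total, _ = integrate.quad(lambda t: repair_rate(p, t), 0, np.inf)
            assert total == pytest.approx(theta, abs=1e-6)

    def test_nonnegative_on_dense_grid(self):
        p = KJMAParams(m=2.3, tau=45, theta=0.9)
        assert np.all(repair_rate(p, np.linspace(0.01, 500, 2000)) >= 0)


class TestLinearize:
    def test_noiseless_points_collinear(self):
        tc = noiseless_course(2.0, 60.0, 0.8)
        x, y = linearize(tc, 0.8)
        slopes = np.diff(y) / np.diff(x)
        assert slopes == pytest.approx([2.0, 2.0], rel=1e-10)

    def test_value_at_tau_maps_to_origin(self):
        tc = noiseless_course(1.7, 60.0, 0.9, times=[20, 60, 120])
        x, y = linearize(tc, 0.9)
        at_tau = np.flatnonzero(np.isclose(x, math.log(60.0)))
        assert y[at_tau] == pytest.approx(0.0, abs=1e-12)

    def test_zero_repair_points_dropped(self):
        tc = RepairTimeCourse(times=[20, 60, 120], values=[0.0, 0.3, 0.5])
        x, y = linearize(tc, 0.8)
        assert len(x) == 2

    def test_infeasible_theta(self):
        tc = RepairTimeCourse(times=[20, 60], values=[0.3, 0.6])
        with pytest.raises(InfeasibleThetaError):
            linearize(tc, 0.5)

    def test_too_few_points(self):
        tc = RepairTimeCourse(times=[20, 60, 120], values=[0.0, 0.0, 0.5])
        with pytest.raises(UnfittableRegionError):
            linearize(tc, 0.8)

    def test_saturated_point_dropped_at_theta_one(self):
        tc = RepairTimeCourse(times=[20, 60, 120], values=[0.3, 0.6, 1.0])
        x, _ = linearize(tc, 1.0)
        assert len(x) == 2


class TestFitGivenTheta:
    def test_noiseless_round_trip(self):
        tc = noiseless_course(2.0, 60.0, 0.8)
        m, tau, adj_r2, n, degen = fit_given_theta(tc, 0.8)
        assert m == pytest.approx(2.0, abs=1e-6)
        assert tau == pytest.approx(60.0, abs=1e-3)
        assert adj_r2 == pytest.approx(1.0, abs=1e-12)
        assert n == 3 and not degen

    def test_two_points_interpolate_degenerately(self):
        tc = RepairTimeCourse(times=[20, 120], values=[0.2, 0.6])
        m, tau, adj_r2, n, degen = fit_given_theta(tc, 0.8)
        assert degen and adj_r2 == 1.0 and n == 2 and m > 0

    def test_decreasing_pairs_invalid(self):
        tc = RepairTimeCourse(times=[20, 60, 120], values=[0.6, 0.4, 0.2])
        # rectification would forbid this; unrectified input must be rejected
        with pytest.raises(ValueError):
            RepairTimeCourse(times=[20, 60], values=[0.6, -0.1])
        assert fit_given_theta(tc, 0.8) is None

    def test_infeasible_theta_is_marker_not_exception(self):
        tc = RepairTimeCourse(times=[20, 60], values=[0.3, 0.6])
        assert fit_given_theta(tc, 0.5) is None


class TestFit:
    def test_grid_round_trip(self):
        tc = noiseless_course(2.0, 60.0, 0.8)
        p = fit(tc, theta_min=0.4)
        assert 0.79 <= p.theta <= 0.81
        assert p.m == pytest.approx(2.0, rel=0.05)
        assert p.adj_r2 == pytest.approx(1.0, abs=1e-9)

    def test_high_repair_restricts_grid(self):
        tc = RepairTimeCourse(times=[20, 60, 120], values=[0.5, 0.8, 0.95])
        p = fit(tc, theta_min=0.4)
        assert p.theta > 0.95

    def test_tie_break_prefers_smallest_theta(self):
        # two points are interpolated exactly by every feasible theta
        tc = RepairTimeCourse(times=[20, 60], values=[0.2, 0.4])
        p = fit(tc, theta_min=0.4)
        assert p.theta == pytest.approx(0.41)
        assert p.degenerate

    def test_invariant_under_point_duplication(self):
        tc = noiseless_course(1.6, 45.0, 0.7)
        doubled = pool_time_courses([tc, tc])
        p1, p2 = fit(tc, 0.4), fit(doubled, 0.4)
        assert p1.m == pytest.approx(p2.m, rel=1e-9)
        assert p1.tau == pytest.approx(p2.tau, rel=1e-9)
        assert p1.theta == p2.theta

    def test_unfittable_region_raises(self):
        tc = RepairTimeCourse(times=[20, 60, 120], values=[0.0, 0.0, 0.0])
        with pytest.raises(UnfittableRegionError):
            fit(tc, theta_min=0.4)

    def test_random_noiseless_triples_recovered(self, rng):
        for _ in range(25):
            m = rng.uniform(0.8, 3.0)
            tau = rng.uniform(30, 150)
            theta = round(rng.uniform(0.5, 0.95), 2)
            p = fit(noiseless_course(m, tau, theta), theta_min=0.4)
            assert p.theta == pytest.approx(theta, abs=1e-9)
            assert p.m == pytest.approx(m, rel=1e-3)
            assert p.tau == pytest.approx(tau, rel=1e-3)
            assert p.adj_r2 == pytest.approx(1.0, abs=1e-9)

    def test_beta_tau_identity(self):
        p = fit(noiseless_course(2.0, 60.0, 0.8), 0.4)
        assert p.beta * p.tau == 1.0


class TestFilterParams:
    @pytest.mark.parametrize(
        "m,tau,expected",
        [(2, 60, True), (0.4, 60, False), (2, 250, False),
         (0.5, 20, True), (5, 200, True), (5.01, 60, False)],
    )
    def test_reasonable_range(self, m, tau, expected):
        assert filter_params(KJMAParams(m=m, tau=tau, theta=0.8)) is expected

    def test_custom_bounds(self):
        p = KJMAParams(m=0.4, tau=60, theta=0.8)
        assert filter_params(p, m_range=(0.1, 5))


class TestFitMany:
    def test_batch_survives_unfittable_region(self):
        good = noiseless_course(2.0, 60.0, 0.8, region_id="ok")
        bad = RepairTimeCourse(times=[20, 60, 120], values=[0, 0, 0],
                               region_id="dead")
        df = fit_many([good, bad], region_class={"ok": "TS_start",
                                                 "dead": "nonTCR"})
        assert list(df["fitted"]) == [True, False]
        ok = df.set_index("region_id").loc["ok"]
        assert ok["passes_filter"] and ok["theta"] == pytest.approx(0.8)

    def test_theta_floor_depends_on_region_class(self):
        # true theta 0.45 is reachable only under the non-transcribed floor
        tc = noiseless_course(2.0, 60.0, 0.45, region_id="r")
        low = fit_many([tc], region_class={"r": "nonTCR"})
        high = fit_many([tc], region_class={"r": "TS_centre"})
        assert low.loc[0, "theta"] == pytest.approx(0.45)
        assert high.loc[0, "theta"] >= 0.5


@settings(max_examples=30, deadline=None, derandomize=True)
@given(
    m=st.floats(0.5, 5.0),
    tau=st.floats(20.0, 200.0),
    theta=st.floats(0.05, 1.0),
    t=st.floats(0.0, 500.0),
)
def test_fraction_within_envelope(m, tau, theta, t):
    p = KJMAParams(m=m, tau=tau, theta=theta)
    val = repair_fraction(p, t)
    assert 0.0 <= val <= theta + 1e-12
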