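"""Closed-form operational-model equations and their derived quantities."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from omafit import (
    OperationalParams,
    apparent_tau,
    blackleff_response,
    ec50_closed_form,
    ec50_exceeds_ka_region,
    hill_oma_response,
    hill_response,
    invert_apparent_tau,
    invert_hill_to_operational,
    observed_emax,
    oma_response,
    two_slope_response,
)
from omafit.fitting import numeric_ec50

GRID = np.logspace(-10, -2, 33)

params_st = st.builds(
    OperationalParams,
    k_a=st.floats(1e-9, 1e-4),
    tau=st.floats(0.01, 50.0),
    slope=st.floats(0.3, 3.0),
)


class TestHyperbolicModel:
    def test_point_values(self):
        # a = K_A, tau = 1 gives one third of the system maximum
        assert oma_response(1e-6, OperationalParams(k_a=1e-6, tau=1.0)) == pytest.approx(1 / 3)
        # direct evaluation at a = K_A with tau = 0.3
        p = OperationalParams(k_a=1e-6, tau=0.3)
        assert oma_response(1e-6, p) == pytest.approx(0.3 / 2.3, rel=1e-12)

    def test_asymptote_and_midpoint(self):
        assert observed_emax("oma", 3.0) == pytest.approx(0.75)
        assert ec50_closed_form("oma", 1e-6, 3.0) == pytest.approx(2.5e-7)
        p = OperationalParams(k_a=1e-6, tau=3.0)
        ec50 = ec50_closed_form("oma", 1e-6, 3.0)
        assert oma_response(ec50, p) == pytest.approx(0.75 / 2, rel=1e-12)

    def test_tau_zero_is_zero_function(self):
        p = OperationalParams(k_a=1e-6, tau=0.0)
        assert np.all(oma_response(GRID, p) == 0)

    def test_domain_errors(self):
        p = OperationalParams(k_a=1e-6, tau=1.0)
        with pytest.raises(ValueError):
            oma_response(-1e-9, p)
        with pytest.raises(ValueError):
            OperationalParams(k_a=-1e-6, tau=1.0)
        with pytest.raises(ValueError):
            OperationalParams(k_a=1e-6, tau=-0.1)
        with pytest.raises(ValueError):
            OperationalParams(k_a=1e-6, tau=1.0, slope=0.0)


class TestBlackLeff:
    @settings(derandomize=True, max_examples=40)
    @given(params_st)
    def test_reduces_to_hyperbola_at_unit_slope(self, p):
        p1 = OperationalParams(k_a=p.k_a, tau=p.tau, slope=1.0)
        np.testing.assert_allclose(
            blackleff_response(GRID, p1), oma_response(GRID, p1), rtol=1e-12
        )

    def test_slope_distorts_observed_maximum(self):
        # strong agonist gains, weak agonist loses, when n rises to 2
        assert observed_emax("blackleff", 10.0, n=2.0) == pytest.approx(0.990, abs=5e-4)
        assert observed_emax("blackleff", 0.1, n=2.0) == pytest.approx(0.0099, abs=5e-5)
        assert observed_emax("blackleff", 10.0, n=1.0) == pytest.approx(10 / 11)

    def test_slope_bidirectionality(self):
        ns = np.linspace(1.0, 3.0, 9)
        strong = [observed_emax("blackleff", 10.0, n=n) for n in ns]
        weak = [observed_emax("blackleff", 0.1, n=n) for n in ns]
        const = [observed_emax("blackleff", 1.0, n=n) for n in ns]
        assert np.all(np.diff(strong) > 0)
        assert np.all(np.diff(weak) < 0)
        np.testing.assert_allclose(const, 0.5, rtol=1e-12)

    def test_a0_is_exactly_zero_for_shallow_slope(self):
        p = OperationalParams(k_a=1e-6, tau=2.0, slope=0.5)
        assert blackleff_response(0.0, p) == 0.0


class TestHill:
    @pytest.mark.parametrize("n_h", [0.3, 1.0, 3.0])
    def test_midpoint_invariance(self, n_h):
        assert hill_response(2e-7, 0.8, 2e-7, n_h) == pytest.approx(0.4, rel=1e-12)

    def test_tenfold_above_midpoint(self):
        assert hill_response(10 * 2e-7, 1.0, 2e-7, 2.0) == pytest.approx(100 / 101)

    @settings(derandomize=True, max_examples=40)
    @given(params_st)
    def test_hill_oma_reduces_at_unit_slope(self, p):
        p1 = OperationalParams(k_a=p.k_a, tau=p.tau, slope=1.0)
        np.testing.assert_allclose(
            hill_oma_response(GRID, p1), oma_response(GRID, p1), rtol=1e-12
        )

    @pytest.mark.parametrize("n_h", [0.5, 1.0, 2.0])
    def test_midpoint_independent_of_slope(self, n_h):
        # EC50 of the Hill-based model stays at K_A/(tau+1) for every n_H
        p = OperationalParams(k_a=1e-6, tau=3.0, slope=n_h)
        ec50 = numeric_ec50(lambda a: hill_oma_response(a, p), 0.75)
        assert ec50 == pytest.approx(2.5e-7, rel=1e-8)

    def test_half_maximum_value(self):
        p = OperationalParams(k_a=1e-6, tau=3.0, slope=2.0)
        assert hill_oma_response(2.5e-7, p) == pytest.approx(0.375, rel=1e-12)

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            hill_response(1e-6, 1.0, -1e-7, 1.0)
        with pytest.raises(ValueError):
            hill_response(1e-6, 1.0, 1e-7, 0.0)


class TestTwoSlope:
    @settings(derandomize=True, max_examples=40)
    @given(params_st)
    def test_reduces_to_blackleff_at_unit_binding_slope(self, p):
        pm = OperationalParams(k_a=p.k_a, tau=p.tau, slope=p.slope, slope_binding=1.0)
        np.testing.assert_allclose(
            two_slope_response(GRID, pm), blackleff_response(GRID, pm), rtol=1e-12
        )

    def test_unit_slopes_give_hyperbola(self):
        pm = OperationalParams(k_a=1e-6, tau=2.0, slope=1.0, slope_binding=1.0)
        np.testing.assert_allclose(
            two_slope_response(GRID, pm), oma_response(GRID, pm), rtol=1e-12
        )

    def test_closed_form_ec50_matches_root(self):
        pm = OperationalParams(k_a=1e-6, tau=1.0, slope=2.0, slope_binding=0.5)
        e_obs = observed_emax("blackleff", 1.0, n=2.0)
        ec50_num = numeric_ec50(lambda a: two_slope_response(a, pm), e_obs)
        ec50_cf = ec50_closed_form("two_slope", 1e-6, 1.0, n=2.0, m=0.5)
        assert ec50_cf == pytest.approx(ec50_num, rel=1e-6)

    def test_missing_binding_slope(self):
        pm = OperationalParams(k_a=1e-6, tau=1.0, slope=2.0)
        with pytest.raises(ValueError):
            two_slope_response(GRID, pm)


class TestClosedFormEC50:
    def test_blackleff_n1_matches_hyperbola(self):
        for tau in (0.1, 1.0, 7.0):
            assert ec50_closed_form("blackleff", 1e-6, tau, n=1.0) == pytest.approx(
                ec50_closed_form("oma", 1e-6, tau), rel=1e-12
            )

    def test_autoinhibition_example(self):
        ec50 = ec50_closed_form("autoinhibition", 1e-6, 0.2, sigma=1.0)
        assert ec50 == pytest.approx(1.5946e-6, rel=1e-4)
        assert -math.log10(ec50) == pytest.approx(5.797, abs=1e-3)

    @settings(derandomize=True, max_examples=25)
    @given(st.floats(0.05, 30.0), st.floats(0.5, 3.0))
    def test_blackleff_matches_numeric_oracle(self, tau, n):
        p = OperationalParams(k_a=1e-6, tau=tau, slope=n)
        e_obs = observed_emax("blackleff", tau, n=n)
        ec50_num = numeric_ec50(lambda a: blackleff_response(a, p), e_obs, bracket=(1e-14, 1e2))
        assert ec50_closed_form("blackleff", 1e-6, tau, n=n) == pytest.approx(
            ec50_num, rel=1e-6
        )

    @settings(derandomize=True, max_examples=25)
    @given(st.floats(0.05, 10.0), st.floats(0.1, 10.0))
    def test_autoinhibition_matches_numeric_oracle(self, tau, sigma):
        from omafit.simulate import autoinhibition_response

        e_obs = observed_emax("autoinhibition", tau, sigma=sigma)
        ec50_num = numeric_ec50(
            lambda a: autoinhibition_response(a, 1e-6, tau, sigma), e_obs, bracket=(1e-14, 1e2)
        )
        assert ec50_closed_form("autoinhibition", 1e-6, tau, sigma=sigma) == pytest.approx(
            ec50_num, rel=1e-6
        )

    @settings(derandomize=True, max_examples=40)
    @given(st.floats(0.01, 100.0))
    def test_hyperbolic_ec50_below_ka(self, tau):
        assert ec50_closed_form("oma", 1e-6, tau) < 1e-6

    def test_monotone_in_tau(self):
        taus = np.linspace(0.1, 20, 25)
        emaxes = [observed_emax("oma", t) for t in taus]
        ec50s = [ec50_closed_form("oma", 1e-6, t) for t in taus]
        assert np.all(np.diff(emaxes) > 0)
        assert np.all(np.diff(ec50s) < 0)


class TestApparentTau:
    def test_closed_forms(self):
        assert apparent_tau("autoinhibition", 0.2, sigma=1.0) == pytest.approx(0.091, abs=5e-4)
        assert apparent_tau("feedback", 5.0, delta=5.0) == pytest.approx(1.154, abs=5e-4)
        assert apparent_tau("feedback", 7.0, delta=1.0) == pytest.approx(7.0, rel=1e-12)

    def test_autoinhibition_symmetry(self):
        assert apparent_tau("autoinhibition", 0.3, sigma=4.0) == pytest.approx(
            apparent_tau("autoinhibition", 4.0, sigma=0.3), rel=1e-12
        )

    @settings(derandomize=True, max_examples=25)
    @given(st.floats(0.05, 20.0), st.floats(0.1, 10.0))
    def test_feedback_inversion_round_trip(self, tau, delta):
        tp = apparent_tau("feedback", tau, delta=delta)
        assert invert_apparent_tau("feedback", tp, delta=delta) == pytest.approx(tau, rel=1e-9)

    @settings(derandomize=True, max_examples=25)
    @given(st.floats(0.05, 20.0), st.floats(0.1, 10.0))
    def test_autoinhibition_inversion_round_trip(self, tau, sigma):
        tp = apparent_tau("autoinhibition", tau, sigma=sigma)
        assert invert_apparent_tau("autoinhibition", tp, sigma=sigma) == pytest.approx(
            tau, rel=1e-9
        )

    def test_unknown_model(self):
        with pytest.raises(ValueError):
            apparent_tau("depletion", 1.0)


class TestHillInversion:
    def test_simple_values(self):
        assert invert_hill_to_operational(0.5, 1e-6) == pytest.approx((1.0, 2e-6))
        tau, k_a = invert_hill_to_operational(0.75, 2.5e-7)
        assert tau == pytest.approx(3.0, rel=1e-12)
        assert k_a == pytest.approx(1e-6, rel=1e-12)

    def test_full_agonist_not_determinable(self):
        tau, k_a = invert_hill_to_operational(1.0, 1e-8)
        assert math.isnan(tau) and math.isnan(k_a)

    @settings(derandomize=True, max_examples=40)
    @given(st.floats(0.01, 50.0), st.floats(1e-9, 1e-4))
    def test_round_trip_with_closed_forms(self, tau, k_a):
        e_obs = observed_emax("oma", tau)
        ec50 = ec50_closed_form("oma", k_a, tau)
        tau2, ka2 = invert_hill_to_operational(e_obs, ec50)
        assert tau2 == pytest.approx(tau, rel=1e-9)
        assert ka2 == pytest.approx(k_a, rel=1e-9)


class TestEC50ExceedsKaBoundary:
    def test_crossing_and_asymptote(self):
        # boundary passes through tau = 1 at n = log2(3) ~ 1.585
        assert ec50_exceeds_ka_region(math.log2(3)) == pytest.approx(1.0, rel=1e-12)
        assert ec50_exceeds_ka_region(50.0) == pytest.approx(2.0, rel=1e-3)
        assert ec50_exceeds_ka_region(1.0) is None
        assert ec50_exceeds_ka_region(0.5) is None
        with pytest.raises(ValueError):
            ec50_exceeds_ka_region(0.0)

    def test_boundary_separates_regimes(self):
        n = 2.0
        tau_star = ec50_exceeds_ka_region(n)
        below = ec50_closed_form("blackleff", 1e-6, tau_star * 0.9, n=n)
        above = ec50_closed_form("blackleff", 1e-6, tau_star * 1.1, n=n)
        assert below > 1e-6 > above
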