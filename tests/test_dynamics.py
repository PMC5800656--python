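"""Pair-approximation rates, ODEs, R0 and equilibria."""

import numpy as np
import pytest

from pairsis import (
    EpidemicParams,
    PairState,
    SpatialMoments,
    Strain,
    basic_reproduction_number,
    endemic_equilibrium,
    force_of_infection,
    global_strain_equilibrium,
    integrate,
    is_endemic,
    r0_via_ngm,
)
from pairsis.dynamics import (
    StrainRates,
    TwoStrainState,
    _deriv_single_arr,
    _deriv_two_arr,
    deriv_single,
    deriv_two_strain,
    endemic_margin_rho_form,
    proportional_mixing_state,
)

from conftest import random_admissible


class TestRates:
    def test_tradeoff_endpoints(self):
        p = EpidemicParams(10, 8, 1)
        for s_exp in (1.0, 0.5, 2.0):
            assert Strain(0.0, s_exp).local_weight == 1.0
            assert Strain(1.0, s_exp).local_weight == 0.0

    def test_rate_partition(self):
        p = EpidemicParams(10, 8, 1)
        r = Strain(0.3).rates(p)
        assert r.g == pytest.approx(3.0)
        assert r.l == pytest.approx(8 * 0.7 * 0.75)
        assert r.psi == pytest.approx(8 * 0.7 * 0.25)
        # within/outside split of local transmission follows theta
        assert r.l / r.psi == pytest.approx((1 - p.theta) / p.theta)


class TestForceOfInfection:
    def test_disease_free_is_zero(self, moments_mid):
        r = StrainRates(4.0, 3.0, 1.0)
        assert force_of_infection(PairState(0, 0, 0), r, moments_mid) == 0.0

    def test_global_only(self):
        # G = 1: phi = beta_G x_I
        m = SpatialMoments(0.5, 0.3)
        r = Strain(1.0).rates(EpidemicParams(10, 10, 1))
        assert force_of_infection(PairState(0.4, 0, 0), r, m) == pytest.approx(4.0)

    def test_local_only(self):
        # G = 0: phi = beta_L (1-theta) p_SI / x_S
        m = SpatialMoments(0.5, 0.3)
        r = Strain(0.0).rates(EpidemicParams(10, 10, 1))
        st = PairState(0.1, 0.1, 0.0)  # x_S = 0.4
        assert force_of_infection(st, r, m) == pytest.approx(7.5 * 0.25)

    def test_inconsistent_state_error(self):
        m = SpatialMoments(0.5, 0.3)
        r = Strain(0.0).rates(EpidemicParams(10, 10, 1))
        with pytest.raises(ValueError, match="x_S"):
            force_of_infection(PairState(0.5, 0.1, 0.0), r, m)


class TestSingleStrainDerivative:
    def test_disease_free_equilibrium(self, params, moments_mid):
        d = deriv_single(PairState(0, 0, 0), Strain(0.7).rates(params), params, moments_mid)
        assert np.all(d == 0.0)

    def test_global_closed_form_is_fixed_point(self, params, moments_mid):
        eq = global_strain_equilibrium(params, moments_mid)
        d = deriv_single(eq, Strain(1.0).rates(params), params, moments_mid)
        assert np.max(np.abs(d)) < 1e-10

    def test_zero_rates_zero_derivative(self, moments_mid):
        p = EpidemicParams(0.0, 0.0, 0.0)
        st = PairState(0.1, 0.05, 0.02)
        d = deriv_single(st, Strain(0.5).rates(p), p, moments_mid)
        assert np.all(d == 0.0)

    def test_invariant_violation_rejected(self, params, moments_mid):
        bad = PairState(0.1, 0.2, 0.2)  # p_II = -0.3
        with pytest.raises(ValueError, match="negative"):
            deriv_single(bad, Strain(0.5).rates(params), params, moments_mid)


class TestTwoStrainDerivative:
    def test_mutant_absent_reduces_to_single(self, params, moments_mid):
        res = Strain(0.6)
        y1 = np.array([0.2, 0.06, 0.05])
        y2 = np.array([0.2, 0.06, 0.05, 0.0, 0.0, 0.0, 0.0])
        d1 = _deriv_single_arr(y1, res.rates(params), params.alpha, moments_mid)
        d2 = _deriv_two_arr(
            y2, res.rates(params), Strain(0.2).rates(params), params.alpha, moments_mid
        )
        assert np.allclose(d2[:3], d1, atol=1e-14)
        assert np.all(d2[3:] == 0.0)

    def test_resident_absent_reduces_to_mutant_single(self, params, moments_mid):
        mut = Strain(0.2)
        y1 = np.array([0.2, 0.06, 0.05])
        # mutant-only pairs: p_SJ acts as p_SI, p_JJ as p_II; p_JO dependent
        y2 = np.array([0.0, 0.0, 0.0, 0.2, 0.06, 0.0, 0.2 - 0.06 - 0.05])
        d1 = _deriv_single_arr(y1, mut.rates(params), params.alpha, moments_mid)
        d2 = _deriv_two_arr(
            y2, Strain(0.9).rates(params), mut.rates(params), params.alpha, moments_mid
        )
        assert d2[3] == pytest.approx(d1[0], abs=1e-14)  # dx_J = dx_I
        assert d2[4] == pytest.approx(d1[1], abs=1e-14)  # dp_SJ = dp_SI
        assert np.allclose(d2[:3], 0.0, atol=1e-14)

    def test_neutral_label_symmetry(self, params, moments_mid):
        """A 50/50 relabelling of one strain as two identical strains
        evolves with the same total density as the single strain."""
        res = Strain(0.6)
        r = res.rates(params)
        y1 = np.array([0.1, 0.05, 0.02])  # p_II = 0.03
        y2 = np.array([0.05, 0.025, 0.01, 0.05, 0.025, 0.0075, 0.0075])
        f1 = lambda y: _deriv_single_arr(y, r, params.alpha, moments_mid)
        f2 = lambda y: _deriv_two_arr(y, r, r, params.alpha, moments_mid)
        t_eval = np.linspace(0, 20, 21)
        sol1 = integrate(f1, y1, (0, 20), t_eval=t_eval)
        sol2 = integrate(f2, y2, (0, 20), t_eval=t_eval)
        assert np.max(np.abs(sol2.y[0] + sol2.y[3] - sol1.y[0])) < 1e-9
        assert np.max(np.abs(sol2.y[1] + sol2.y[4] - sol1.y[1])) < 1e-9

    def test_two_strain_state_validation(self, moments_mid):
        with pytest.raises(ValueError, match="negative"):
            TwoStrainState(0.1, 0.2, 0.2, 0, 0, 0, 0).validate(moments_mid)


class TestIntegration:
    def test_dfe_is_constant(self, params, moments_mid):
        r = Strain(0.5).rates(params)
        f = lambda y: _deriv_single_arr(y, r, params.alpha, moments_mid)
        sol = integrate(f, np.zeros(3), (0, 50), t_eval=np.linspace(0, 50, 6))
        assert np.all(sol.y == 0.0)

    def test_converges_to_global_closed_form(self, params, moments_mid):
        r = Strain(1.0).rates(params)
        f = lambda y: _deriv_single_arr(y, r, params.alpha, moments_mid)
        y0 = proportional_mixing_state(0.005, moments_mid).as_array()
        sol = integrate(f, y0, (0, 200))
        eq = global_strain_equilibrium(params, moments_mid)
        assert np.allclose(sol.y[:, -1], eq.as_array(), atol=1e-8)

    def test_trajectory_admissible(self, params, moments_mid, rng):
        """Reconstructed densities stay non-negative along trajectories
        (the pair-sum identities hold identically by reconstruction)."""
        for G in (0.0, 0.4, 1.0):
            r = Strain(G).rates(params)
            f = lambda y: _deriv_single_arr(y, r, params.alpha, moments_mid)
            y0 = proportional_mixing_state(0.01, moments_mid).as_array()
            sol = integrate(f, y0, (0, 100), t_eval=np.linspace(0, 100, 51))
            for y in sol.y.T:
                PairState(*y).validate(moments_mid, tol=1e-8)


class TestR0:
    def test_global_limit(self):
        p = EpidemicParams(10, 10, 4)
        m = SpatialMoments(0.5, 0.3)
        assert basic_reproduction_number(Strain(1.0), p, m) == pytest.approx(1.25)

    def test_local_limit(self):
        p = EpidemicParams(10, 10, 1)
        m = SpatialMoments(0.5, 0.4)
        assert basic_reproduction_number(Strain(0.0), p, m) == pytest.approx(6.0)

    def test_no_transmission(self):
        p = EpidemicParams(0, 0, 1)
        m = SpatialMoments(0.5, 0.3)
        assert basic_reproduction_number(Strain(0.5), p, m) == 0.0
        assert r0_via_ngm(Strain(0.5), p, m) == pytest.approx(0.0, abs=1e-12)

    def test_alpha_zero_rejected(self):
        with pytest.raises(ValueError):
            basic_reproduction_number(
                Strain(0.5), EpidemicParams(10, 10, 0), SpatialMoments(0.5, 0.3)
            )

    def test_ngm_matches_closed_form(self, rng):
        for _ in range(100):
            strain, p, m = random_admissible(rng)
            closed = basic_reproduction_number(strain, p, m)
            ngm = r0_via_ngm(strain, p, m)
            assert abs(closed - ngm) < 1e-8 * max(1.0, closed)

    def test_r0_nonincreasing_in_alpha(self, rng):
        strain, p, m = random_admissible(rng)
        alphas = np.linspace(0.2, 8.0, 15)
        vals = [
            basic_reproduction_number(strain, EpidemicParams(p.beta_G, p.beta_L, a), m)
            for a in alphas
        ]
        assert np.all(np.diff(vals) <= 1e-12)


class TestEndemicCondition:
    def test_threshold_examples(self):
        m = SpatialMoments(0.5, 0.3)
        assert not is_endemic(Strain(1.0), EpidemicParams(10, 10, 5.5), m)[0]
        assert is_endemic(Strain(1.0), EpidemicParams(10, 10, 4.0), m)[0]

    def test_tiny_alpha_always_endemic(self):
        m = SpatialMoments(0.5, 0.3)
        assert is_endemic(Strain(0.5), EpidemicParams(10, 10, 1e-6), m)[0]

    def test_margin_sign_iff_r0(self, rng):
        for _ in range(100):
            strain, p, m = random_admissible(rng)
            endemic, margin = is_endemic(strain, p, m)
            r0 = basic_reproduction_number(strain, p, m)
            if abs(r0 - 1.0) > 1e-10:
                assert endemic == (r0 > 1.0), (margin, r0)

    def test_rho_form_agrees(self, rng):
        for _ in range(50):
            strain, p, m = random_admissible(rng)
            if not 0.01 < strain.G < 0.99:
                continue
            assert endemic_margin_rho_form(strain, p, m) == is_endemic(strain, p, m)[0]


class TestEquilibria:
    def test_global_closed_form_values(self):
        p = EpidemicParams(10, 10, 1)
        m = SpatialMoments(0.5, 0.3)
        eq = global_strain_equilibrium(p, m)
        assert eq.x_I == pytest.approx(0.4)
        assert eq.p_SI == pytest.approx(0.048)
        assert eq.p_IO == pytest.approx(0.16)

    def test_global_threshold_degenerate(self):
        p = EpidemicParams(10, 10, 5.0)  # alpha = beta_G x_C exactly
        m = SpatialMoments(0.5, 0.3)
        eq = global_strain_equilibrium(p, m)
        assert eq.x_I == 0.0
        assert global_strain_equilibrium(EpidemicParams(10, 10, 6), m) is None

    def test_numeric_matches_closed_form(self, rng):
        for _ in range(5):
            _, p, m = random_admissible(rng, endemic_for="global")
            num = endemic_equilibrium(Strain(1.0), p, m)
            closed = global_strain_equilibrium(p, m)
            assert np.allclose(num.as_array(), closed.as_array(), atol=1e-6)

    def test_subcritical_reports_extinct(self):
        p = EpidemicParams(10, 10, 6.0)
        m = SpatialMoments(0.5, 0.3)
        assert endemic_equilibrium(Strain(1.0), p, m) is None

    def test_seed_insensitivity(self, params, moments_mid):
        a = endemic_equilibrium(Strain(0.4), params, moments_mid, seed_fraction=0.01)
        b = endemic_equilibrium(Strain(0.4), params, moments_mid, seed_fraction=0.3)
        assert np.allclose(a.as_array(), b.as_array(), atol=1e-8)
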