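"""Fixed points, Jacobian spectra, scenario battery and bifurcation scans."""

import numpy as np
import pytest

import distwm
from distwm.params import ModelParams
from distwm.stability import (bifurcation_scan, fixed_point, gradient_sweep,
                              isolated_jacobian, isolated_persistence,
                              isolated_rhs, jacobian_eigs, scenario_battery,
                              simulate_isolated_area)

P = ModelParams()


def finite_difference_jacobian(S, params, g_EI, g_II, eps=1e-7):
    J = np.zeros((3, 3))
    for j in range(3):
        up, dn = np.array(S, float), np.array(S, float)
        up[j] += eps
        dn[j] -= eps
        J[:, j] = (isolated_rhs(up, params, g_EI, g_II)
                   - isolated_rhs(dn, params, g_EI, g_II)) / (2 * eps)
    return J


class TestFixedPoint:
    def test_matches_ode_relaxation(self):
        S_star = fixed_point(P, PV=0.0, branch="low", g_EI_override=0.0)
        _, _, S_series = simulate_isolated_area(P, PV=0.0, T=5.0,
                                                g_EI_override=0.0)
        assert np.abs(S_series[-1] - S_star).max() < 1e-6

    def test_low_branch_exists_with_inhibition(self):
        S_star = fixed_point(P, PV=0.0, branch="low")
        assert np.abs(isolated_rhs(S_star, P, 0.192, 0.105)).max() < 1e-10
        assert S_star.max() < 0.1

    def test_one_population_caricature_closed_form(self):
        # linear phi caricature: S* = gamma r tau / (1 + gamma r tau)
        r = 10.0
        S_star = P.gamma * r * P.tau_N / (1 + P.gamma * r * P.tau_N)
        resid = -S_star / P.tau_N + P.gamma * (1 - S_star) * r
        assert abs(resid) < 1e-12


class TestJacobianEigs:
    def test_printed_reference_eigenvalues(self):
        S = fixed_point(P, PV=0.0)
        ev = jacobian_eigs(S, P, PV=0.0).real
        assert np.allclose(np.round(ev, 1), [-10.4, -12.5, -229.8])

    def test_printed_no_inhibition_eigenvalues(self):
        S = fixed_point(P, PV=0.0, g_EI_override=0.0)
        ev = jacobian_eigs(S, P, PV=0.0, g_EI_override=0.0).real
        assert np.allclose(np.round(ev, 1), [-7.4, -7.9, -232.3])

    def test_block_triangular_invariance_without_gEI(self):
        # with g_EI = 0 the E-block decouples: leading pair ignores g_II, PV
        ref = None
        for g_II, PV in [(0.105, 0.0), (0.3, 0.0), (0.105, 1.0), (0.2, 0.6)]:
            S = fixed_point(P, PV=PV, g_EI_override=0.0, g_II_override=g_II)
            ev = jacobian_eigs(S, P, PV=PV, g_EI_override=0.0,
                               g_II_override=g_II).real
            if ref is None:
                ref = ev[:2]
            assert np.allclose(ev[:2], ref, atol=1e-8)

    def test_matches_finite_differences_at_random_stable_points(self):
        rng = np.random.default_rng(0)
        checked = 0
        while checked < 100:
            p = P.replace(g_E_self=float(rng.uniform(0.3, 0.5)),
                          g_EI_0=float(rng.uniform(0.15, 0.4)),
                          I0_A=float(rng.uniform(0.28, 0.33)),
                          I0_B=float(rng.uniform(0.28, 0.33)))
            PV = float(rng.uniform(0, 1))
            try:
                S = fixed_point(p, PV=PV)
            except RuntimeError:
                continue
            from distwm.dynamics import local_inhibitory_weights
            g_EI, g_II = map(float, local_inhibitory_weights(PV, p))
            J = isolated_jacobian(S, p, g_EI, g_II)
            if np.linalg.eigvals(J).real.max() >= 0:
                continue
            J_fd = finite_difference_jacobian(S, p, g_EI, g_II)
            denom = np.abs(J).max()
            assert np.abs(J - J_fd).max() / denom < 1e-4
            checked += 1

    def test_eigen_verdicts_agree_with_forward_integration(self):
        # stable spectrum <=> small perturbations decay
        rng = np.random.default_rng(1)
        agree = 0
        for _ in range(20):
            p = P.replace(g_E_self=float(rng.uniform(0.3, 0.62)),
                          g_EI_0=float(rng.uniform(0.1, 0.5)))
            PV = float(rng.uniform(0, 1))
            try:
                S = fixed_point(p, PV=PV)
            except RuntimeError:
                continue
            ev = jacobian_eigs(S, p, PV=PV).real
            _, _, S_series = simulate_isolated_area(
                p, PV=PV, T=2.0, S0=np.clip(S + 1e-3, 0, 1))
            drifted = np.abs(S_series[-1] - S).max() > 1e-2
            assert (ev.max() < 0) == (not drifted)
            agree += 1
        assert agree >= 10


@pytest.fixture(scope="module")
def reports(default_connectome):
    return scenario_battery(default_connectome, P)


class TestScenarioBattery:
    def test_five_scenario_verdicts(self, reports):
        stable = [r.stable for r in reports]
        # isolated circuits stable with and without inhibition; the coupled
        # network needs long-range E-to-I and local inhibition
        assert stable == [True, True, True, False, False]

    def test_unstable_scenarios_reach_high_rates(self, reports):
        assert reports[3].steady_rates.max() > 20.0
        assert reports[4].steady_rates.max() > 20.0


class TestIsolatedPersistence:
    def test_alternative_regime_bistable_at_low_pv(self):
        assert isolated_persistence(ModelParams.alternative(), PV=0.0)

    def test_reference_regime_never_persists(self):
        for PV in (0.0, 0.5, 1.0):
            assert not isolated_persistence(P, PV=PV)

    def test_strong_inhibition_suppresses(self):
        p = ModelParams.alternative().replace(g_EI_0=5.0)
        assert not isolated_persistence(p, PV=0.0)


class TestGradientSweep:
    def test_pv_mean_equals_default_for_constant_pv(self, reference_params):
        from conftest import make_connectome
        rng = np.random.default_rng(2)
        W = rng.random((4, 4))
        np.fill_diagonal(W, 0)
        conn = make_connectome(W / W.max(), np.full(4, 0.5),
                               np.array([0.0, 0.3, 0.7, 1.0]))
        grid_g0 = [0.192]
        grid_sc = [0.83]
        c1, s1 = gradient_sweep(conn, reference_params, grid_g0, grid_sc,
                                "default")
        c2, s2 = gradient_sweep(conn, reference_params, grid_g0, grid_sc,
                                "pv_mean")
        assert np.array_equal(c1, c2) and np.array_equal(s1, s2)

    def test_counts_non_increasing_in_base_inhibition(self, small_connectome,
                                                      reference_params):
        counts, _ = gradient_sweep(small_connectome, reference_params,
                                   [0.15, 0.192, 0.3], [0.83], "default")
        col = counts[:, 0]
        assert (np.diff(col) <= 0).all()


class TestBifurcationScan:
    def test_alternative_regime_has_critical_value(self):
        p = ModelParams.alternative()
        crit = bifurcation_scan(p, PV=0.0, g_range=(0.0, 0.5))
        assert crit is not None and 0.0 < crit < 0.5

    def test_reference_regime_low_state_survives_without_inhibition(self):
        crit = bifurcation_scan(P, PV=0.0, g_range=(0.0, 0.192))
        assert crit is None

    def test_critical_value_monotone_in_self_excitation(self):
        crit_06 = bifurcation_scan(ModelParams.alternative(), PV=0.0)
        crit_055 = bifurcation_scan(
            ModelParams.alternative().replace(g_E_self=0.55), PV=0.0)
        assert crit_06 > crit_055
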