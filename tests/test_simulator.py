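"""Network integration: protocols, reproducibility, delay-rate quantification."""

import numpy as np
import pytest

import distwm
from distwm.simulator import (Protocol, correlate_measure, delay_rates,
                              initial_state_from, long_range_currents,
                              persistent_areas, simulate)

from conftest import make_connectome


class TestLongRangeCurrents:
    def test_zero_gating_gives_zero_currents(self, toy):
        _, _, conn = toy
        I_A, I_B, I_C = long_range_currents(np.zeros(2), np.zeros(2),
                                            conn.W_E, conn.W_I, 0.1, 0.167)
        assert not I_A.any() and not I_B.any() and not I_C.any()

    def test_single_edge_product(self, toy):
        _, _, conn = toy
        S_A = np.array([1.0, 0.0])      # source = area 0 ('low')
        I_A, _, _ = long_range_currents(S_A, np.zeros(2), conn.W_E, conn.W_I,
                                        0.1, 0.167)
        assert np.isclose(I_A[1], 0.1 * conn.W_E[1, 0])

    def test_inhibitory_row_sum(self, toy):
        _, _, conn = toy
        S = np.full(2, 0.5)
        _, _, I_C = long_range_currents(S, S, conn.W_E, conn.W_I, 0.1, 0.167)
        assert np.allclose(I_C, 0.167 * 0.5 * 2 * conn.W_I.sum(axis=1))


class TestSimulate:
    def test_same_seed_bit_identical(self, small_connectome, reference_params):
        proto = Protocol.visual_delay_task(small_connectome.names[0],
                                           params=reference_params, seed=5)
        t1 = simulate(small_connectome, reference_params, proto)
        t2 = simulate(small_connectome, reference_params, proto)
        for p in "ABC":
            assert np.array_equal(t1.r[p], t2.r[p])
            assert np.array_equal(t1.S[p], t2.S[p])

    def test_stable_baseline_without_stimulus(self, small_connectome,
                                              reference_params):
        proto = Protocol(stimulus_targets=(), T_trial=10.0, seed=0)
        traj = simulate(small_connectome, reference_params, proto,
                        deterministic=True)
        early = traj.r["A"][int(1.9 / proto.dt)]
        late = traj.r["A"][-1]
        assert np.abs(late - early).max() < 1.0

    def test_nmda_gating_stays_in_unit_interval(self, small_connectome,
                                                reference_params):
        proto = Protocol.visual_delay_task(small_connectome.names[0],
                                           params=reference_params, seed=1)
        traj = simulate(small_connectome, reference_params, proto)
        for p in "AB":
            assert traj.S[p].min() >= 0.0 and traj.S[p].max() <= 1.0
        assert (traj.r[p] >= 0).all()

    def test_step_halving_convergence(self, small_connectome, reference_params):
        area = small_connectome.names[0]
        p_half = reference_params
        p_full = reference_params.replace(dt=0.001)
        r = {}
        for p in (p_half, p_full):
            proto = Protocol.visual_delay_task(area, params=p)
            traj = simulate(small_connectome, p, proto, deterministic=True)
            r[p.dt] = delay_rates(traj)
        denom = max(1.0, np.abs(r[0.0005]).max())
        assert np.abs(r[0.0005] - r[0.001]).max() / denom < 0.01

    def test_decoupled_network_factorizes(self, reference_params):
        # with mu_EE = mu_IE = 0 a joint run equals per-area runs exactly
        rng = np.random.default_rng(0)
        W = rng.random((4, 4))
        np.fill_diagonal(W, 0)
        PV = np.array([0.0, 0.3, 0.7, 1.0])
        h = np.array([0.0, 0.4, 0.8, 1.0])
        conn = make_connectome(W / W.max(), PV, h)
        p = reference_params.replace(mu_EE=0.0, mu_IE=0.0)
        proto = Protocol.visual_delay_task(conn.names[1], params=p)
        joint = simulate(conn, p, proto, deterministic=True)
        sub = make_connectome(np.zeros((2, 2)), PV[[1, 2]], h[[1, 2]],
                              atlas_names=[conn.names[1], conn.names[2]])
        alone = simulate(sub, p, proto, deterministic=True)
        assert np.array_equal(joint.r["A"][:, [1, 2]], alone.r["A"])
        assert np.array_equal(joint.S["C"][:, [1, 2]], alone.S["C"])

    def test_stimulated_population_dominates_unstimulated(self, small_connectome,
                                                          reference_params):
        proto = Protocol.visual_delay_task(small_connectome.names[0], "A",
                                           params=reference_params)
        traj = simulate(small_connectome, reference_params, proto,
                        deterministic=True)
        i_stim = int(2.2 / proto.dt)
        assert traj.r["A"][i_stim, 0] > traj.r["B"][i_stim, 0]
        assert (traj.r["A"] + 1e-12 >= traj.r["B"]).all()

    def test_restart_from_final_state_is_continuous(self, small_connectome,
                                                    reference_params):
        proto = Protocol(stimulus_targets=(), T_trial=3.0)
        t1 = simulate(small_connectome, reference_params, proto,
                      deterministic=True)
        t2 = simulate(small_connectome, reference_params, proto,
                      deterministic=True, initial=initial_state_from(t1))
        # already at the baseline fixed point: state barely moves
        assert np.abs(t2.r["A"][-1] - t1.r["A"][-1]).max() < 1e-3

    def test_unknown_stimulus_area_raises(self, small_connectome,
                                          reference_params):
        proto = Protocol(stimulus_targets=(("nope", "A"),))
        with pytest.raises(KeyError):
            simulate(small_connectome, reference_params, proto)


class TestDelayRates:
    def _traj_with_series(self, series, dt=0.01, T=10.0, T_off=2.5):
        proto = Protocol(stimulus_targets=(), T_on=2.0, T_off=T_off,
                         T_trial=T, dt=dt)
        n = series.shape[1]
        return distwm.Trajectory(
            t=np.arange(series.shape[0]) * dt, names=[f"a{i}" for i in range(n)],
            r={"A": series, "B": series, "C": series},
            S={"A": series, "B": series, "C": series},
            params=distwm.ModelParams(), protocol=proto)

    def test_constant_series(self):
        series = np.full((1001, 2), 7.0)
        traj = self._traj_with_series(series)
        assert np.allclose(delay_rates(traj), 7.0)

    def test_linear_ramp_closed_form(self):
        dt, T = 0.01, 10.0
        t = np.arange(0, T + dt / 2, dt)
        series = (10.0 * t / T)[:, None]
        traj = self._traj_with_series(series, dt=dt, T=T)
        # mean of the ramp over [8, 9.5] s
        expected = 10.0 / T * (8.0 + 9.5) / 2
        assert np.isclose(delay_rates(traj)[0], expected, rtol=1e-3)

    def test_short_delay_rejected(self):
        series = np.full((1001, 1), 1.0)
        traj = self._traj_with_series(series, T_off=9.0)
        with pytest.raises(ValueError):
            delay_rates(traj)


class TestPersistence:
    def test_threshold_rule_and_tie(self):
        flags = persistent_areas(np.array([0.3, 6.2, 5.0]), 5.0)
        assert flags.tolist() == [False, True, False]

    def test_recount_matches_trajectory(self, small_connectome, reference_params):
        proto = Protocol.visual_delay_task(small_connectome.names[0],
                                           params=reference_params)
        traj = simulate(small_connectome, reference_params, proto,
                        deterministic=True)
        rates = delay_rates(traj)
        i0 = int(round(8.0 / proto.dt))
        i1 = int(round(9.5 / proto.dt))
        brute = traj.r["A"][i0:i1 + 1].mean(axis=0)
        assert np.array_equal(persistent_areas(rates),
                              persistent_areas(brute))


class TestCorrelateMeasure:
    def test_perfect_correlations(self):
        x = np.arange(10.0)
        assert correlate_measure(x, x)[0] == pytest.approx(1.0)
        assert correlate_measure(x, -x)[0] == pytest.approx(-1.0)

    def test_matches_covariance_formula(self):
        rng = np.random.default_rng(1)
        x, y = rng.random(10), rng.random(10)
        r, _ = correlate_measure(x, y)
        xc, yc = x - x.mean(), y - y.mean()
        expect = (xc @ yc) / np.sqrt((xc @ xc) * (yc @ yc))
        assert abs(r - expect) < 1e-12

    def test_subset_and_errors(self):
        x = np.array([1.0, 2, 3, 4])
        with pytest.raises(ValueError):
            correlate_measure(x, x, subset=np.array([True, True, False, False]))
        with pytest.raises(ValueError):
            correlate_measure(np.ones(5), np.arange(5.0))
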