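"""Stochastic network simulation and delay-period quantification.

The network couples the local circuits of :mod:`distwm.dynamics` through the
CIB-split connectivity: NMDA gating of source excitatory populations drives
same-selectivity excitatory targets (scaled by ``mu_EE * W_E``) and the
shared inhibitory population of each target (scaled by ``mu_IE * W_I``).
Integration is forward Euler-Maruyama at ``dt``; all state variables start
from zero, and the interval before stimulus onset serves as burn-in to the
baseline fixed point.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .connectome import Connectome
from .dynamics import local_inhibitory_weights, phi_E, phi_I
from .params import ModelParams

__all__ = [
    "InhibitionEvent",
    "Protocol",
    "Trajectory",
    "long_range_currents",
    "initial_state_from",
    "simulate",
    "delay_rates",
    "persistent_areas",
    "correlate_measure",
]


@dataclass(frozen=True)
class InhibitionEvent:
    """Simulated-optogenetics inhibition of a set of areas.

    ``phase='stimulus'`` covers [T_on, T_off); ``phase='delay'`` starts 2 s
    after stimulus offset and lasts until trial end. Cortical targets receive
    the current on their inhibitory population; thalamic targets (no local
    inhibition) receive it, negated, on both excitatory populations.
    """

    areas: tuple[str, ...]
    phase: str = "delay"
    current: float = 5.0          # nA
    population: str = "C"

    def window(self, params: ModelParams) -> tuple[float, float]:
        if self.phase == "stimulus":
            return params.T_on, params.T_off
        if self.phase == "delay":
            return params.T_off + 2.0, params.T_trial
        raise ValueError(f"unknown inhibition phase {self.phase!r}")


@dataclass(frozen=True)
class Protocol:
    """Stimulation protocol of one trial.

    ``stimulus_targets`` lists (area name, population) pairs receiving
    ``I_stim`` during the half-open window [T_on, T_off).
    """

    stimulus_targets: tuple[tuple[str, str], ...] = ()
    I_stim: float = 0.5
    T_on: float = 2.0
    T_off: float = 2.5
    T_trial: float = 10.0
    dt: float = 0.0005
    seed: int = 0
    inhibition_events: tuple[InhibitionEvent, ...] = ()

    def __post_init__(self):
        if not (0 <= self.T_on < self.T_off <= self.T_trial):
            raise ValueError("need 0 <= T_on < T_off <= T_trial")
        if self.dt <= 0:
            raise ValueError("dt must be positive")

    @classmethod
    def visual_delay_task(cls, stimulus_area: str, population: str = "A",
                          params: ModelParams | None = None, seed: int = 0,
                          inhibition_events=()) -> "Protocol":
        """Standard delayed-response trial: pulse one area, then a delay."""
        p = params or ModelParams()
        return cls(stimulus_targets=((stimulus_area, population),),
                   I_stim=p.I_stim, T_on=p.T_on, T_off=p.T_off,
                   T_trial=p.T_trial, dt=p.dt, seed=seed,
                   inhibition_events=tuple(inhibition_events))


@dataclass
class Trajectory:
    """Time-resolved state of one simulation (cortex, optionally thalamus)."""

    t: np.ndarray
    names: list[str]
    r: dict                      # population -> (n_steps+1, n_areas) Hz
    S: dict                      # population -> gating series
    params: ModelParams
    protocol: Protocol
    thal_names: list[str] = field(default_factory=list)
    r_th: dict = field(default_factory=dict)
    S_th: dict = field(default_factory=dict)

    @property
    def n_areas(self) -> int:
        return len(self.names)


def long_range_currents(S_A, S_B, W_E, W_I, mu_EE: float, mu_IE: float):
    """Long-range currents (A, B, C) onto every area, nA.

    Excitatory targets receive only same-selectivity gating; the inhibitory
    population receives the selectivity sum.
    """
    S_A = np.asarray(S_A, float)
    S_B = np.asarray(S_B, float)
    if W_E.shape[1] != S_A.shape[0]:
        raise ValueError("gating vector length does not match connectome")
    I_A = mu_EE * (W_E @ S_A)
    I_B = mu_EE * (W_E @ S_B)
    I_C = mu_IE * (W_I @ (S_A + S_B))
    return I_A, I_B, I_C


def _event_masks(protocol: Protocol, params: ModelParams, names: list[str],
                 thal_names: list[str]):
    """Precompute (window, current-vector) pairs for stimulus and inhibition."""
    n, n_th = len(names), len(thal_names)
    stim = {"A": np.zeros(n), "B": np.zeros(n)}
    for area, pop in protocol.stimulus_targets:
        if pop not in stim:
            raise ValueError(f"stimulus population must be 'A' or 'B', got {pop!r}")
        if area in names:
            stim[pop][names.index(area)] += protocol.I_stim
        else:
            raise KeyError(f"unknown stimulus area {area!r}")
    inh_cortex, inh_thal = [], []
    for ev in protocol.inhibition_events:
        t0, t1 = ev.window(params)
        vec_c, vec_t = np.zeros(n), np.zeros(n_th)
        for area in ev.areas:
            if area in names:
                vec_c[names.index(area)] += ev.current
            elif area in thal_names:
                # no thalamic interneurons: hyperpolarize both E populations
                vec_t[thal_names.index(area)] -= ev.current
            else:
                raise KeyError(f"unknown inhibition target {area!r}")
        if vec_c.any():
            inh_cortex.append((t0, t1, vec_c))
        if vec_t.any():
            inh_thal.append((t0, t1, vec_t))
    return stim, inh_cortex, inh_thal


def initial_state_from(traj: Trajectory) -> dict:
    """Final state of a trajectory, usable as ``simulate(..., initial=...)``."""
    state = {"S_" + p: traj.S[p][-1] for p in "ABC"}
    state.update({"r_" + p: traj.r[p][-1] for p in "ABC"})
    if traj.thal_names:
        state["S_th"] = np.column_stack([traj.S_th["A"][-1], traj.S_th["B"][-1]])
        state["r_th"] = np.column_stack([traj.r_th["A"][-1], traj.r_th["B"][-1]])
    return state


def simulate(connectome: Connectome, params: ModelParams, protocol: Protocol,
             pv_mode: str = "gradient", deterministic: bool = False,
             thalamus=None, initial: dict | None = None) -> Trajectory:
    """Integrate the network with the Euler-Maruyama scheme.

    Parameters
    ----------
    pv_mode : 'gradient' or 'mean'
        'mean' replaces every area's PV fraction by the cortical average
        (the gradient-removal control).
    deterministic : bool
        Force all noise amplitudes to zero (exact, seed-independent runs).
    thalamus : ThalamicNetwork, optional
        Adds AMPA-mediated thalamocortical coupling; see
        :mod:`distwm.thalamus`.
    initial : dict, optional
        Starting state (see :func:`initial_state_from`); defaults to all
        variables at zero.

    Raises
    ------
    FloatingPointError
        If any state variable becomes non-finite, reporting the step index.
    """
    names = connectome.names
    n = connectome.n_areas
    dt = protocol.dt
    n_steps = int(round(protocol.T_trial / dt))
    rng = np.random.default_rng(protocol.seed)

    g_EI, g_II = local_inhibitory_weights(connectome.PV, params, pv_mode)
    W_E, W_I = connectome.W_E, connectome.W_I
    mu_EE, mu_IE = params.mu_EE, params.mu_IE
    sig_E = 0.0 if deterministic else np.array([params.sigma_A, params.sigma_B])
    sig_C = 0.0 if deterministic else params.sigma_C
    noisy_E = not deterministic and (params.sigma_A or params.sigma_B)
    noisy_C = not deterministic and params.sigma_C

    th = thalamus
    thal_names = list(th.names) if th is not None else []
    stim, inh_cortex, inh_thal = _event_masks(protocol, params, names, thal_names)
    stim_E = np.column_stack([stim["A"], stim["B"]])   # (n, 2)

    # populations A and B are the two columns of the (n, 2) E-state arrays
    S_E = np.zeros((n, 2)); S_C = np.zeros(n)
    r_E = np.zeros((n, 2)); r_C = np.zeros(n)
    x_E = np.zeros((n, 2)); x_C = np.zeros(n)
    if initial is not None:
        S_E = np.column_stack([initial["S_A"], initial["S_B"]]).astype(float)
        S_C = np.asarray(initial["S_C"], float).copy()
        r_E = np.column_stack([initial["r_A"], initial["r_B"]]).astype(float)
        r_C = np.asarray(initial["r_C"], float).copy()

    out_r_E = np.zeros((n_steps + 1, n, 2)); out_r_C = np.zeros((n_steps + 1, n))
    out_S_E = np.zeros((n_steps + 1, n, 2)); out_S_C = np.zeros((n_steps + 1, n))
    out_r_E[0], out_r_C[0] = r_E, r_C
    out_S_E[0], out_S_C[0] = S_E, S_C
    if th is not None:
        n_th = len(thal_names)
        S_th = np.zeros((n_th, 2)); r_th = np.zeros((n_th, 2))
        if initial is not None and "S_th" in initial:
            S_th = np.asarray(initial["S_th"], float).copy()
            r_th = np.asarray(initial["r_th"], float).copy()
        out_r_th = np.zeros((n_steps + 1, n_th, 2))
        out_S_th = np.zeros((n_steps + 1, n_th, 2))
        out_r_th[0], out_S_th[0] = r_th, S_th
        W_tc_E, W_tc_I = th.W_tc_E, th.W_tc_I
        W_ct_E = th.W_ct_E
        g_E_tc, g_I_tc, g_ct, I_th0 = th.g_E_tc, th.g_I_tc, th.g_ct, th.I_th0
        tau_A_th, gamma_A = th.tau_A, th.gamma_A

    tau_r, tau_N, tau_G, tau_noise = params.tau_r, params.tau_N, params.tau_G, params.tau_noise
    gamma, gamma_I = params.gamma, params.gamma_I
    gEs, gEc, gIE = params.g_E_self, params.g_E_cross, params.g_IE
    I0_E = np.array([params.I0_A, params.I0_B])
    I0C = params.I0_C
    a_fi, b_fi, d_fi = params.a, params.b, params.d
    c1_gI, r0_I, c0 = params.c1 / params.g_I, params.r0_I, params.c0
    g_EI_col = g_EI[:, None]
    sqrt_dt = np.sqrt(dt)
    T_on, T_off = protocol.T_on, protocol.T_off
    decay = 1.0 - dt / tau_noise
    check_every = 50

    with np.errstate(over="ignore"):
        for k in range(n_steps):
            t = k * dt
            I_E = (gEs * S_E + gEc * S_E[:, ::-1] - g_EI_col * S_C[:, None]
                   + I0_E + mu_EE * (W_E @ S_E) + x_E)
            if T_on <= t < T_off:
                I_E = I_E + stim_E
            sum_E = S_E[:, 0] + S_E[:, 1]
            I_C = gIE * sum_E - g_II * S_C + I0C + mu_IE * (W_I @ sum_E) + x_C
            for t0, t1, vec in inh_cortex:
                if t0 <= t < t1:
                    I_C = I_C + vec

            if th is not None:
                I_E = I_E + g_E_tc * (W_tc_E @ S_th)
                I_C = I_C + g_I_tc * (W_tc_I @ (S_th[:, 0] + S_th[:, 1]))
                I_th = g_ct * (W_ct_E @ S_E) + I_th0
                for t0, t1, vec in inh_thal:
                    if t0 <= t < t1:
                        I_th = I_th + vec[:, None]

            # inline phi_E on the stacked E currents (removable singularity is
            # a measure-zero event; the series branch lives in dynamics.phi_E)
            u = a_fi * I_E - b_fi
            phiE = u / (1.0 - np.exp(-d_fi * u))
            phiC = np.maximum(0.0, (params.c1 * I_C - c0) / params.g_I + r0_I)

            new_r_E = r_E + (dt / tau_r) * (phiE - r_E)
            new_r_C = r_C + (dt / tau_r) * (phiC - r_C)
            new_S_E = S_E + dt * (-S_E / tau_N + gamma * (1.0 - S_E) * r_E)
            new_S_C = S_C + dt * (-S_C / tau_G + gamma_I * r_C)

            x_E = x_E * decay
            x_C = x_C * decay
            if noisy_E:
                x_E = x_E + sig_E * sqrt_dt * rng.standard_normal((n, 2))
            if noisy_C:
                x_C = x_C + sig_C * sqrt_dt * rng.standard_normal(n)

            if th is not None:
                u_th = a_fi * I_th - b_fi
                phi_th = u_th / (1.0 - np.exp(-d_fi * u_th))
                new_r_th = r_th + (dt / tau_r) * (phi_th - r_th)
                S_th = S_th + dt * (-S_th / tau_A_th + gamma_A * r_th)
                r_th = new_r_th

            r_E, r_C = new_r_E, new_r_C
            S_E, S_C = new_S_E, new_S_C

            j = k + 1
            out_r_E[j] = r_E; out_r_C[j] = r_C
            out_S_E[j] = S_E; out_S_C[j] = S_C
            if th is not None:
                out_r_th[j] = r_th
                out_S_th[j] = S_th

            if j % check_every == 0 or j == n_steps:
                if not np.isfinite(S_E).all() or not np.isfinite(S_C).all() \
                        or not np.isfinite(r_E).all():
                    raise FloatingPointError(
                        f"non-finite state by step {j} (t={j * dt:.4f} s)")
                if (S_E < 0.0).any() or (S_E > 1.0).any():
                    raise FloatingPointError(f"NMDA gating left [0,1] by step {j}")

    out_r = {"A": out_r_E[:, :, 0], "B": out_r_E[:, :, 1], "C": out_r_C}
    out_S = {"A": out_S_E[:, :, 0], "B": out_S_E[:, :, 1], "C": out_S_C}
    t_grid = np.arange(n_steps + 1) * dt
    traj = Trajectory(t=t_grid, names=names, r=out_r, S=out_S,
                      params=params, protocol=protocol)
    if th is not None:
        traj.thal_names = thal_names
        traj.r_th = {"A": out_r_th[:, :, 0], "B": out_r_th[:, :, 1]}
        traj.S_th = {"A": out_S_th[:, :, 0], "B": out_S_th[:, :, 1]}
    return traj


def delay_rates(traj: Trajectory, population: str = "A",
                thalamic: bool = False) -> np.ndarray:
    """Mean firing rate over the late-delay window, per area (Hz).

    The window runs from 2 s before trial end to 0.5 s before trial end,
    after activity has settled into its post-stimulus state.
    """
    proto = traj.protocol
    T_trial, T_off, dt = proto.T_trial, proto.T_off, proto.dt
    if T_trial - T_off < 2.0:
        raise ValueError("delay period shorter than the 2 s averaging lead-in")
    i0 = int(round((T_trial - 2.0) / dt))
    i1 = int(round((T_trial - 0.5) / dt))
    series = traj.r_th[population] if thalamic else traj.r[population]
    if i1 > len(series) - 1:
        raise ValueError("averaging window extends past the trajectory")
    return series[i0:i1 + 1].mean(axis=0)


def persistent_areas(rates: np.ndarray, theta: float = 5.0) -> np.ndarray:
    """Boolean flags: delay rate strictly above the persistence threshold."""
    if theta <= 0:
        raise ValueError("threshold must be positive")
    return np.asarray(rates, float) > theta


def correlate_measure(values: np.ndarray, covariate: np.ndarray,
                      subset: np.ndarray | None = None) -> tuple[float, float]:
    """Pearson correlation (r, two-sided p) over an optional area subset."""
    values = np.asarray(values, float)
    covariate = np.asarray(covariate, float)
    if subset is not None:
        subset = np.asarray(subset, bool)
        values, covariate = values[subset], covariate[subset]
    if len(values) < 3:
        raise ValueError("need at least three points for a correlation")
    if np.ptp(values) == 0 or np.ptp(covariate) == 0:
        raise ValueError("zero variance in correlation input")
    r, p = stats.pearsonr(values, covariate)
    return float(r), float(p)
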