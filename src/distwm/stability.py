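"""Fixed points, Jacobian spectra and baseline-stability analyses.

For an isolated area (no long-range input, no noise) the firing rates relax
much faster than the NMDA gating (tau_r << tau_N), so rates are slaved to
their transfer functions and the area reduces to a three-dimensional system
in the gating variables (S_A, S_B, S_C):

    dS_A/dt = -S_A/tau_N + gamma (1-S_A) phi_E(g_E,self S_A + g_E,cross S_B
              - g_EI S_C + I0_A)                                   = F_A
    dS_B/dt = (symmetric)                                          = F_B
    dS_C/dt = -S_C/tau_G + gamma_I phi_I(g_IE (S_A+S_B) - g_II S_C
              + I0_C)                                              = F_C

Baseline stability is the spectrum of the analytic Jacobian of (F_A, F_B,
F_C) at the low-activity fixed point. Network-level scenarios (long-range
connections intact or selectively removed) are assessed by noise-free
forward simulation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import root

from .connectome import Connectome
from .dynamics import (local_inhibitory_weights, phi_E, phi_E_prime, phi_I,
                       phi_I_prime)
from .params import ModelParams
from .simulator import Protocol, delay_rates, persistent_areas, simulate

__all__ = [
    "StabilityReport",
    "isolated_rhs",
    "isolated_jacobian",
    "fixed_point",
    "jacobian_eigs",
    "scenario_battery",
    "isolated_persistence",
    "gradient_sweep",
    "bifurcation_scan",
    "simulate_isolated_area",
]

_KINK_TOL = 1e-6  # nA distance to the phi_I rectification kink


def _local_weights(params: ModelParams, PV: float,
                   g_EI_override=None, g_II_override=None) -> tuple[float, float]:
    g_EI, g_II = local_inhibitory_weights(PV, params)
    if g_EI_override is not None:
        g_EI = g_EI_override
    if g_II_override is not None:
        g_II = g_II_override
    return float(g_EI), float(g_II)


def isolated_rhs(S, params: ModelParams, g_EI: float, g_II: float,
                 I_ext=(0.0, 0.0, 0.0)) -> np.ndarray:
    """(F_A, F_B, F_C) of the reduced isolated-area system."""
    SA, SB, SC = S
    IA = params.g_E_self * SA + params.g_E_cross * SB - g_EI * SC + params.I0_A + I_ext[0]
    IB = params.g_E_self * SB + params.g_E_cross * SA - g_EI * SC + params.I0_B + I_ext[1]
    IC = params.g_IE * (SA + SB) - g_II * SC + params.I0_C + I_ext[2]
    return np.array([
        -SA / params.tau_N + params.gamma * (1.0 - SA) * phi_E(IA, params),
        -SB / params.tau_N + params.gamma * (1.0 - SB) * phi_E(IB, params),
        -SC / params.tau_G + params.gamma_I * phi_I(IC, params),
    ])


def isolated_jacobian(S, params: ModelParams, g_EI: float, g_II: float,
                      I_ext=(0.0, 0.0, 0.0)) -> np.ndarray:
    """Analytic 3x3 Jacobian of :func:`isolated_rhs` (chain rule)."""
    SA, SB, SC = S
    IA = params.g_E_self * SA + params.g_E_cross * SB - g_EI * SC + params.I0_A + I_ext[0]
    IB = params.g_E_self * SB + params.g_E_cross * SA - g_EI * SC + params.I0_B + I_ext[1]
    IC = params.g_IE * (SA + SB) - g_II * SC + params.I0_C + I_ext[2]
    kink_distance = abs((params.c0 - params.g_I * params.r0_I) / params.c1 - IC)
    if kink_distance < _KINK_TOL:
        raise ValueError("fixed point sits at the phi_I rectification kink; "
                         "the Jacobian is not differentiable there")
    dpA, dpB = phi_E_prime(IA, params), phi_E_prime(IB, params)
    dpC = phi_I_prime(IC, params)
    g, gI_ = params.gamma, params.gamma_I
    J = np.empty((3, 3))
    J[0, 0] = -1.0 / params.tau_N + g * (-phi_E(IA, params) + (1 - SA) * dpA * params.g_E_self)
    J[0, 1] = g * (1 - SA) * dpA * params.g_E_cross
    J[0, 2] = g * (1 - SA) * dpA * (-g_EI)
    J[1, 0] = g * (1 - SB) * dpB * params.g_E_cross
    J[1, 1] = -1.0 / params.tau_N + g * (-phi_E(IB, params) + (1 - SB) * dpB * params.g_E_self)
    J[1, 2] = g * (1 - SB) * dpB * (-g_EI)
    J[2, 0] = gI_ * dpC * params.g_IE
    J[2, 1] = gI_ * dpC * params.g_IE
    J[2, 2] = -1.0 / params.tau_G + gI_ * dpC * (-g_II)
    return J


_GUESSES = {"low": np.zeros(3), "high": np.array([0.7, 0.7, 0.3])}


def fixed_point(params: ModelParams, PV: float = 0.0, branch: str = "low",
                g_EI_override=None, g_II_override=None,
                I_ext=(0.0, 0.0, 0.0), residual_tol: float = 1e-10) -> np.ndarray:
    """Gating triple (S_A, S_B, S_C) of an isolated-area fixed point.

    ``branch`` selects the initial guess: 'low' starts from the origin (the
    baseline state), 'high' from elevated symmetric gating.
    """
    if branch not in _GUESSES:
        raise ValueError("branch must be 'low' or 'high'")
    g_EI, g_II = _local_weights(params, PV, g_EI_override, g_II_override)
    sol = root(isolated_rhs, _GUESSES[branch],
               args=(params, g_EI, g_II, I_ext),
               jac=isolated_jacobian, method="hybr", tol=1e-13)
    # accept on residual: hybr can flag "not making progress" at the root
    resid = np.abs(isolated_rhs(sol.x, params, g_EI, g_II, I_ext)).max()
    if resid > residual_tol:
        raise RuntimeError(
            f"fixed-point solver failed on branch {branch!r}: "
            f"success={sol.success}, residual={resid:.3e}, message={sol.message}")
    return sol.x


def jacobian_eigs(S, params: ModelParams, PV: float = 0.0,
                  g_EI_override=None, g_II_override=None,
                  I_ext=(0.0, 0.0, 0.0)) -> np.ndarray:
    """Eigenvalues (s^-1) of the isolated-area Jacobian at a fixed point.

    Complex-capable; sorted by real part in descending order.
    """
    g_EI, g_II = _local_weights(params, PV, g_EI_override, g_II_override)
    J = isolated_jacobian(S, params, g_EI, g_II, I_ext)
    ev = np.linalg.eigvals(J)
    return ev[np.argsort(-ev.real)]


def simulate_isolated_area(params: ModelParams, PV: float = 0.0,
                           I_stim: float = 0.0, T: float | None = None,
                           g_EI_override=None, g_II_override=None,
                           S0=(0.0, 0.0, 0.0), dt: float | None = None):
    """Noise-free forward integration of one isolated area (full r/S system).

    A stimulus current ``I_stim`` is applied to population A during
    [T_on, T_off). Returns ``(t, r_A, S)`` with S the (n_steps+1, 3) gating
    series; used as the ODE-relaxation oracle for the fixed-point solver and
    by the independent-persistence test.
    """
    dt = dt or params.dt
    T = T or params.T_trial
    g_EI, g_II = _local_weights(params, PV, g_EI_override, g_II_override)
    n_steps = int(round(T / dt))
    S = np.array(S0, float)
    r = np.zeros(3)
    out_r = np.zeros(n_steps + 1)
    out_S = np.zeros((n_steps + 1, 3))
    out_S[0] = S
    for k in range(n_steps):
        t = k * dt
        ext = I_stim if params.T_on <= t < params.T_off else 0.0
        IA = params.g_E_self * S[0] + params.g_E_cross * S[1] - g_EI * S[2] + params.I0_A + ext
        IB = params.g_E_self * S[1] + params.g_E_cross * S[0] - g_EI * S[2] + params.I0_B
        IC = params.g_IE * (S[0] + S[1]) - g_II * S[2] + params.I0_C
        new_r = r + dt * (-r + np.array([phi_E(IA, params), phi_E(IB, params),
                                         phi_I(IC, params)])) / params.tau_r
        S = S + dt * np.array([
            -S[0] / params.tau_N + params.gamma * (1 - S[0]) * r[0],
            -S[1] / params.tau_N + params.gamma * (1 - S[1]) * r[1],
            -S[2] / params.tau_G + params.gamma_I * r[2]])
        r = new_r
        out_r[k + 1] = r[0]
        out_S[k + 1] = S
    return np.arange(n_steps + 1) * dt, out_r, out_S


@dataclass
class StabilityReport:
    """Outcome of one stability scenario."""

    scenario: str
    stable: bool
    steady_rates: np.ndarray | None = None       # per-area Hz (network scenarios)
    fixed_points: list = field(default_factory=list)
    eigenvalues: list = field(default_factory=list)
    bistable: np.ndarray | None = None


_SCENARIOS = {
    1: "isolated",
    2: "isolated, no local inhibition",
    3: "full network",
    4: "no long-range E-to-I",
    5: "no local inhibition, long-range intact",
}


def scenario_battery(connectome: Connectome, params: ModelParams,
                     theta: float = 5.0, seed: int = 0) -> list[StabilityReport]:
    """Baseline stability under the five local/long-range scenarios.

    (1) no long-range input; (2) no long-range and g_EI,0 = 0; (3) intact
    network; (4) long-range E-to-I removed (mu_IE = 0); (5) local inhibition
    removed (g_EI,0 = 0) with long-range intact. Isolated scenarios are
    solved analytically per area; network scenarios by noise-free simulation
    with no stimulus. Divergence counts as unstable, never an exception.
    """
    reports = []
    for scen in (1, 2):
        p = params if scen == 1 else params.replace(g_EI_0=0.0)
        fps, eigs, stable = [], [], True
        for PV in connectome.PV:
            S = fixed_point(p, PV=float(PV), branch="low")
            ev = jacobian_eigs(S, p, PV=float(PV))
            fps.append(S)
            eigs.append(ev)
            stable = stable and bool((ev.real < 0).all())
        reports.append(StabilityReport(scenario=_SCENARIOS[scen], stable=stable,
                                       fixed_points=fps, eigenvalues=eigs))
    for scen in (3, 4, 5):
        if scen == 3:
            p = params
        elif scen == 4:
            p = params.replace(mu_IE=0.0)
        else:
            p = params.replace(g_EI_0=0.0)
        proto = Protocol(stimulus_targets=(), T_on=params.T_on,
                         T_off=params.T_off, T_trial=params.T_trial,
                         dt=params.dt, seed=seed)
        try:
            traj = simulate(connectome, p, proto, deterministic=True)
            rates = delay_rates(traj)
            stable = bool((rates <= theta).all())
        except FloatingPointError:
            rates, stable = None, False
        reports.append(StabilityReport(scenario=_SCENARIOS[scen], stable=stable,
                                       steady_rates=rates))
    return reports


def isolated_persistence(params: ModelParams, PV: float = 0.0,
                         theta: float = 5.0,
                         g_EI_override=None, g_II_override=None) -> bool:
    """Does one isolated area sustain delay activity after a stimulus pulse?

    Noise-free stimulation with I_stim during [T_on, T_off); the flag is
    whether the delay-window mean rate exceeds ``theta``.
    """
    t, r_A, _ = simulate_isolated_area(params, PV=PV, I_stim=params.I_stim,
                                       g_EI_override=g_EI_override,
                                       g_II_override=g_II_override)
    dt = params.dt
    i0 = int(round((params.T_trial - 2.0) / dt))
    i1 = int(round((params.T_trial - 0.5) / dt))
    return bool(r_A[i0:i1 + 1].mean() > theta)


def gradient_sweep(connectome: Connectome, params: ModelParams,
                   g_EI0_grid, scaling_grid, condition: str = "default",
                   stimulus_area: str | None = None, theta: float = 5.0,
                   seed: int = 0):
    """Persistent-area counts and baseline-stability mask over a weight grid.

    For every (g_EI,0, g_EI,scaling) cell, a no-stimulus noise-free trial
    determines whether the baseline is stable (no area above ``theta``), and
    a stimulated trial counts persistent areas. ``condition`` selects the
    control: 'pv_mean' replaces the PV gradient by its average, 'cib_mean'
    replaces the CIB coefficients by 0.5.

    Returns ``(counts, stable_mask)`` arrays of shape
    (len(g_EI0_grid), len(scaling_grid)).
    """
    if condition not in ("default", "pv_mean", "cib_mean"):
        raise ValueError(f"unknown condition {condition!r}")
    conn = connectome.with_mean_cib() if condition == "cib_mean" else connectome
    pv_mode = "mean" if condition == "pv_mean" else "gradient"
    if stimulus_area is None:
        stimulus_area = conn.names[int(np.argmin(conn.h))]
    g_EI0_grid = np.atleast_1d(np.asarray(g_EI0_grid, float))
    scaling_grid = np.atleast_1d(np.asarray(scaling_grid, float))
    counts = np.zeros((len(g_EI0_grid), len(scaling_grid)), int)
    stable = np.zeros_like(counts, dtype=bool)
    for i, g0 in enumerate(g_EI0_grid):
        for j, sc in enumerate(scaling_grid):
            p = params.replace(g_EI_0=float(g0), g_EI_scaling=float(sc))
            base_proto = Protocol(stimulus_targets=(), T_on=p.T_on, T_off=p.T_off,
                                  T_trial=p.T_trial, dt=p.dt, seed=seed)
            stim_proto = Protocol.visual_delay_task(stimulus_area, params=p, seed=seed)
            try:
                base = delay_rates(simulate(conn, p, base_proto,
                                            pv_mode=pv_mode, deterministic=True))
                stable[i, j] = bool((base <= theta).all())
                stim = delay_rates(simulate(conn, p, stim_proto,
                                            pv_mode=pv_mode, deterministic=True))
                counts[i, j] = int(persistent_areas(stim, theta).sum())
            except FloatingPointError:
                stable[i, j] = False
                counts[i, j] = len(conn.names)
    return counts, stable


def bifurcation_scan(params: ModelParams, PV: float = 0.0,
                     g_range: tuple[float, float] = (0.0, 0.5),
                     tol: float = 1e-4, relax_T: float = 4.0,
                     theta: float = 5.0) -> float | None:
    """Critical g_EI,0 where the low-activity baseline state disappears.

    Scanning downward in g_EI,0, the low fixed point is deemed absent when
    the root finder fails from the low guess AND noise-free relaxation from
    the origin escapes to high rates. Returns the bisection-refined critical
    value (largest g_EI,0 without a low state), or None if the low state
    exists throughout the range.
    """

    def low_state_exists(g0: float) -> bool:
        p = params.replace(g_EI_0=float(g0))
        try:
            S = fixed_point(p, PV=PV, branch="low")
            solver_ok = bool(np.abs(S).max() < 0.3)
        except RuntimeError:
            solver_ok = False
        _, r_A, _ = simulate_isolated_area(p, PV=PV, I_stim=0.0, T=relax_T)
        relax_low = bool(r_A[-1] < theta)
        return solver_ok or relax_low

    lo, hi = g_range
    if not low_state_exists(hi):
        raise ValueError("low state absent at the top of the scan range")
    if low_state_exists(lo):
        return None
    a, b = lo, hi  # absent at a, present at b
    while b - a > tol:
        mid = 0.5 * (a + b)
        if low_state_exists(mid):
            b = mid
        else:
            a = mid
    return 0.5 * (a + b)
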