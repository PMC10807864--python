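"""Local-circuit dynamics primitives.

Each cortical area contains two stimulus-selective excitatory populations
(A, B) coupled through NMDA gating variables, and one shared inhibitory
population (C) coupled through a GABA gating variable. These functions are
shared by the network simulator, the thalamocortical extension and the
stability analysis.

Sign convention: inhibitory currents enter the total-current equations with a
minus sign (``-g_EI * S_C`` etc.). All quantities are in seconds, nA and Hz.
"""

from __future__ import annotations

import numpy as np

from .params import ModelParams

__all__ = [
    "phi_E",
    "phi_E_prime",
    "phi_I",
    "phi_I_prime",
    "local_inhibitory_weights",
    "total_currents",
    "synapse_derivatives",
    "rate_relaxation",
    "ou_step",
]

# below this |a*I - b| the excitatory transfer function switches to its
# series expansion around the removable singularity
_SINGULARITY_EPS = 1e-9


def phi_E(I, params: ModelParams):
    """Excitatory f-I curve ``(aI-b) / (1 - exp(-d(aI-b)))`` in Hz.

    Continuous, strictly increasing and positive for finite input; the
    removable singularity at ``aI = b`` evaluates to ``1/d``.
    """
    u = np.asarray(params.a * np.asarray(I, dtype=float) - params.b)
    small = np.abs(u) < _SINGULARITY_EPS
    # avoid 0/0 in the vectorized branch
    u_safe = np.where(small, 1.0, u)
    out = np.where(small, 1.0 / params.d + u / 2.0,
                   u_safe / (1.0 - np.exp(-params.d * u_safe)))
    return out if out.shape else float(out)


def phi_E_prime(I, params: ModelParams):
    """Derivative of :func:`phi_E` with respect to current (Hz/nA)."""
    u = np.asarray(params.a * np.asarray(I, dtype=float) - params.b)
    small = np.abs(u) < 1e-6
    u_safe = np.where(small, 1.0, u)
    e = np.exp(-params.d * u_safe)
    out = np.where(small, params.a / 2.0,
                   params.a * ((1.0 - e) - u_safe * params.d * e) / (1.0 - e) ** 2)
    return out if out.shape else float(out)


def phi_I(I, params: ModelParams):
    """Inhibitory f-I curve ``[(c1*I - c0)/g_I + r0_I]_+`` in Hz."""
    out = np.maximum(0.0, (params.c1 * np.asarray(I, dtype=float) - params.c0) / params.g_I
                     + params.r0_I)
    return out if out.shape else float(out)


def phi_I_prime(I, params: ModelParams):
    """Derivative of :func:`phi_I`: ``c1/g_I`` on the active branch, else 0."""
    active = (params.c1 * np.asarray(I, dtype=float) - params.c0) / params.g_I + params.r0_I > 0
    out = np.where(active, params.c1 / params.g_I, 0.0)
    return out if out.shape else float(out)


def local_inhibitory_weights(PV, params: ModelParams, mode: str = "gradient"):
    """Local inhibitory weights scaled by the PV interneuron fraction.

    ``g_EI,i = g_EI,0 (1 + g_EI,scaling * PV_i)`` and likewise for g_II.
    With ``mode='mean'`` every area uses the cortical mean PV fraction
    instead of its own value (the gradient-removal control).

    Returns ``(g_EI, g_II)``, arrays if PV is an array.
    """
    PV = np.asarray(PV, dtype=float)
    if mode == "mean":
        PV = np.full_like(PV, PV.mean()) if PV.ndim else PV
    elif mode != "gradient":
        raise ValueError(f"unknown PV mode {mode!r}")
    g_EI = params.g_EI_0 * (1.0 + params.g_EI_scaling * PV)
    g_II = params.g_II_0 * (1.0 + params.g_II_scaling * PV)
    return g_EI, g_II


def total_currents(S_A, S_B, S_C, g_EI, g_II, params: ModelParams,
                   I_LR=(0.0, 0.0, 0.0), I_ext=(0.0, 0.0, 0.0),
                   noise=(0.0, 0.0, 0.0)):
    """Total currents (I_A, I_B, I_C) onto the three local populations, nA.

    ``I_LR``, ``I_ext`` and ``noise`` are (A, B, C) tuples of per-area
    contributions from long-range input, external protocol input and the
    OU noise process.
    """
    I_A = (params.g_E_self * S_A + params.g_E_cross * S_B - g_EI * S_C
           + params.I0_A + I_LR[0] + I_ext[0] + noise[0])
    I_B = (params.g_E_self * S_B + params.g_E_cross * S_A - g_EI * S_C
           + params.I0_B + I_LR[1] + I_ext[1] + noise[1])
    I_C = (params.g_IE * (S_A + S_B) - g_II * S_C
           + params.I0_C + I_LR[2] + I_ext[2] + noise[2])
    return I_A, I_B, I_C


def synapse_derivatives(S_A, S_B, S_C, r_A, r_B, r_C, params: ModelParams):
    """Time derivatives of the gating variables (per second).

    NMDA gating saturates at 1 (the growth term is proportional to ``1-S``);
    GABA gating grows linearly with the inhibitory rate.
    """
    dS_A = -S_A / params.tau_N + params.gamma * (1.0 - S_A) * r_A
    dS_B = -S_B / params.tau_N + params.gamma * (1.0 - S_B) * r_B
    dS_C = -S_C / params.tau_G + params.gamma_I * r_C
    return dS_A, dS_B, dS_C


def rate_relaxation(r_A, r_B, r_C, I_A, I_B, I_C, params: ModelParams):
    """Firing-rate relaxation toward the transfer-function steady state."""
    dr_A = (-r_A + phi_E(I_A, params)) / params.tau_r
    dr_B = (-r_B + phi_E(I_B, params)) / params.tau_r
    dr_C = (-r_C + phi_I(I_C, params)) / params.tau_r
    return dr_A, dr_B, dr_C


def ou_step(x, dt: float, sigma, params: ModelParams, rng: np.random.Generator):
    """One Euler-Maruyama step of the Ornstein-Uhlenbeck noise current.

    ``x_{t+dt} = x + (-x/tau_noise) dt + sigma sqrt(dt) N(0,1)``; the
    stationary standard deviation is ``sigma * sqrt(tau_noise/2)``. With
    ``sigma = 0`` the current decays deterministically as exp(-t/tau_noise).
    """
    x = np.asarray(x, dtype=float)
    if np.ndim(sigma) == 0 and sigma == 0.0:
        return x * (1.0 - dt / params.tau_noise)
    xi = rng.standard_normal(x.shape if x.shape else None)
    return x + (-x / params.tau_noise) * dt + np.asarray(sigma) * np.sqrt(dt) * xi
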