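"""Thalamocortical extension of the cortical network.

Thalamic nuclei carry two stimulus-selective excitatory populations with
AMPA gating, no local inhibitory population and no thalamo-thalamic
recurrence. The thalamic reticular nucleus enters only as a constant
background current. Cortico-thalamic and thalamo-cortical projections are
rescaled like the cortical weights (power-law then max-normalization, but
without the per-neuron volume/density normalization, which the thalamic
tracer data do not support) and carry their own CIB coefficients built from
the cortical and thalamic hierarchy scores on a common scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .atlas import AreaAtlas
from .connectome import Connectome, cib_matrix, minmax_normalize, split_by_target
from .params import ModelParams, TCParams
from .simulator import Protocol, Trajectory, simulate

__all__ = ["ThalamicNetwork", "tc_matrices", "build_thalamic_network",
           "thalamic_step", "simulate_tc"]


def _rescale_rect(W_raw: np.ndarray, k_scale: float) -> np.ndarray:
    W_raw = np.asarray(W_raw, float)
    if (W_raw < 0).any():
        raise ValueError("raw weights must be nonnegative")
    W = np.power(W_raw, k_scale, where=W_raw > 0, out=np.zeros_like(W_raw))
    peak = W.max()
    if peak <= 0:
        raise ValueError("cannot rescale an all-zero matrix")
    return W / peak


def tc_matrices(W_ct_raw: np.ndarray, W_tc_raw: np.ndarray,
                h: np.ndarray, h_th: np.ndarray, beta: float = 2.42,
                k_scale: float = 0.3):
    """CIB-scaled thalamocortical coupling matrices.

    Parameters are the raw cortex->thalamus matrix (thalamus-by-cortex), the
    raw thalamus->cortex matrix (cortex-by-thalamus), the normalized cortical
    hierarchy and the thalamic hierarchy on the cortical scale.

    Returns ``(W_ct_E, W_ct_I, W_tc_E, W_tc_I)``. ``W_ct_I`` is computed for
    completeness but unused by the dynamics: thalamic areas have no
    inhibitory population.
    """
    W_ct = _rescale_rect(W_ct_raw, k_scale)
    W_tc = _rescale_rect(W_tc_raw, k_scale)
    m_ct = cib_matrix(h_th, beta, h_source=h)      # target thalamic, source cortical
    m_tc = cib_matrix(h, beta, h_source=h_th)      # target cortical, source thalamic
    if m_ct.shape != W_ct.shape or m_tc.shape != W_tc.shape:
        raise ValueError("hierarchy vectors do not match matrix shapes")
    W_ct_E, W_ct_I = split_by_target(W_ct, m_ct)
    W_tc_E, W_tc_I = split_by_target(W_tc, m_tc)
    return W_ct_E, W_ct_I, W_tc_E, W_tc_I


@dataclass
class ThalamicNetwork:
    """Thalamic areas plus their coupling to a cortical connectome."""

    names: list[str]
    h_th: np.ndarray
    W_ct_E: np.ndarray          # thalamus-by-cortex, E-targeting
    W_ct_I: np.ndarray          # stored for completeness, unused by dynamics
    W_tc_E: np.ndarray          # cortex-by-thalamus, onto E populations
    W_tc_I: np.ndarray          # cortex-by-thalamus, onto the I population
    g_ct: float
    g_E_tc: float
    g_I_tc: float
    I_th0: float
    tau_A: float
    gamma_A: float

    @property
    def n_areas(self) -> int:
        return len(self.names)


def build_thalamic_network(thal_table: pd.DataFrame, W_ct_raw: np.ndarray,
                           W_tc_raw: np.ndarray, connectome: Connectome,
                           params: ModelParams | None = None) -> ThalamicNetwork:
    """Assemble the thalamic side of a thalamocortical model.

    Thalamic hierarchy scores are normalized with the *cortical* raw
    hierarchy bounds, so they live on the cortical scale (and may exceed
    [0, 1] for nuclei outside the cortical range). Missing thalamic scores
    are filled with the nearest known neighbor in table order.
    """
    params = params or ModelParams()
    tc: TCParams = params.tc
    h_th_raw = thal_table["hierarchy_raw"].to_numpy(float)
    h_th_raw = _fill_nearest(h_th_raw)
    cortical_raw = connectome.atlas.hierarchy_raw
    # bounds from the cortical raw hierarchy that produced connectome.h
    lo, hi = np.nanmin(cortical_raw), np.nanmax(cortical_raw)
    h_th = minmax_normalize(h_th_raw, bounds=(lo, hi))
    W_ct_E, W_ct_I, W_tc_E, W_tc_I = tc_matrices(
        W_ct_raw, W_tc_raw, connectome.h, h_th, params.beta, params.k_scale)
    return ThalamicNetwork(
        names=thal_table["name"].tolist(), h_th=h_th,
        W_ct_E=W_ct_E, W_ct_I=W_ct_I, W_tc_E=W_tc_E, W_tc_I=W_tc_I,
        g_ct=tc.g_ct, g_E_tc=tc.g_E_tc, g_I_tc=tc.g_I_tc, I_th0=tc.I_th0,
        tau_A=tc.tau_A, gamma_A=tc.gamma_A)


def _fill_nearest(values: np.ndarray) -> np.ndarray:
    """Replace NaNs with the nearest known value in the (user-ordered) list."""
    v = np.array(values, float)
    known = np.flatnonzero(np.isfinite(v))
    if known.size == 0:
        raise ValueError("no thalamic hierarchy values known")
    for i in np.flatnonzero(~np.isfinite(v)):
        v[i] = v[known[np.argmin(np.abs(known - i))]]
    return v


def thalamic_step(S_th: np.ndarray, r_th: np.ndarray, I_ct: np.ndarray,
                  params: ModelParams, tc: TCParams, dt: float):
    """One Euler step of an isolated thalamic population set.

    ``I_ct`` is the corticothalamic drive (already scaled by g_ct) plus the
    background current. The rate relaxes to the excitatory transfer function
    of the total current; AMPA gating integrates ``-S/tau_A + gamma_A r``
    (linear in the rate, unbounded — unlike saturating NMDA gating).
    """
    from .dynamics import phi_E
    new_r = r_th + dt * (-r_th + phi_E(I_ct, params)) / params.tau_r
    new_S = S_th + dt * (-S_th / tc.tau_A + tc.gamma_A * r_th)
    return new_S, new_r


def simulate_tc(connectome: Connectome, thalamus: ThalamicNetwork,
                params: ModelParams, protocol: Protocol,
                pv_mode: str = "gradient", deterministic: bool = False) -> Trajectory:
    """Simulate cortex + thalamus jointly.

    Thalamic inhibition events (targets named in ``protocol`` that belong to
    the thalamus) apply a hyperpolarizing current to both thalamic excitatory
    populations.
    """
    return simulate(connectome, params, protocol, pv_mode=pv_mode,
                    deterministic=deterministic, thalamus=thalamus)
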