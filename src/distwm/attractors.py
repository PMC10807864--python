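"""Attractor census via exhaustive subset stimulation.

Stimulating every subset of a candidate area list (all members receive the
stimulus pulse simultaneously, noise-free) drives the network into whatever
self-sustained state that input pattern selects. Thresholding each run's
delay rates at ``theta`` yields a binary pattern over all areas; distinct
patterns are distinct attractors. The all-low pattern is the baseline state
and is recorded separately, not counted as an attractor.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .connectome import Connectome
from .graph import loop_strength
from .params import ModelParams
from .perturbation import inhibition_effect, run_inhibition
from .simulator import Protocol, delay_rates, persistent_areas, simulate

__all__ = [
    "AttractorSet",
    "enumerate_attractors",
    "attractor_stats",
    "sweep_attractors",
    "attractor_core_analysis",
    "rank_candidates",
]


@dataclass
class AttractorSet:
    """Deduplicated attractor patterns of one parameter setting."""

    names: list[str]
    candidates: list[str]
    theta: float
    patterns: list[tuple[int, ...]] = field(default_factory=list)
    rates: list[np.ndarray] = field(default_factory=list)          # representative delay rates
    discovery_stimulus: list[tuple[str, ...]] = field(default_factory=list)
    baseline_found: bool = False
    parameters: tuple = ()

    @property
    def n_attractors(self) -> int:
        return len(self.patterns)


def rank_candidates(connectome: Connectome, k: int = 18) -> list[str]:
    """Top-k candidate areas by (hierarchy - PV) rank sum.

    High-hierarchy, low-PV areas are the likeliest to participate in
    persistent states; candidates remain an explicit user choice, this is
    only the default ranking.
    """
    from scipy.stats import rankdata
    score = rankdata(connectome.h) + rankdata(-connectome.PV)
    order = np.argsort(-score, kind="stable")
    return [connectome.names[i] for i in order[:k]]


def enumerate_attractors(connectome: Connectome, params: ModelParams,
                         candidates, theta: float = 5.0,
                         budget: int = 1 << 16, sample: int | None = None,
                         seed: int = 0, population: str = "A") -> AttractorSet:
    """Stimulate every candidate subset and collect the distinct patterns.

    Each subset's members all receive ``I_stim`` on population A during
    [T_on, T_off); runs are noise-free, so the census is deterministic.
    With 2^k subsets above ``budget``, pass ``sample`` for a seeded random
    subsample of subsets (the empty subset is always included).
    """
    candidates = list(candidates)
    k = len(candidates)
    n_subsets = 1 << k
    subsets = None
    if n_subsets > budget:
        if sample is None:
            raise ValueError(f"2^{k} subsets exceed budget={budget}; pass sample=N")
        rng = np.random.default_rng(seed)
        picks = rng.integers(0, n_subsets, size=sample)
        subsets = sorted(set(picks.tolist()) | {0})
    else:
        subsets = range(n_subsets)

    aset = AttractorSet(names=connectome.names, candidates=candidates, theta=theta,
                        parameters=(params.mu_EE, params.g_E_self))
    seen: set[tuple[int, ...]] = set()
    for code in subsets:
        members = tuple(candidates[i] for i in range(k) if code >> i & 1)
        proto = Protocol(stimulus_targets=tuple((a, population) for a in members),
                         I_stim=params.I_stim, T_on=params.T_on, T_off=params.T_off,
                         T_trial=params.T_trial, dt=params.dt, seed=seed)
        traj = simulate(connectome, params, proto, deterministic=True)
        rates = delay_rates(traj, population)
        pattern = tuple(int(v) for v in persistent_areas(rates, theta))
        if not any(pattern):
            aset.baseline_found = True
            continue
        if pattern in seen:
            continue
        seen.add(pattern)
        aset.patterns.append(pattern)
        aset.rates.append(rates)
        aset.discovery_stimulus.append(members)
    return aset


def attractor_stats(aset: AttractorSet) -> dict:
    """Per-area attractor fractions and the attractor-size histogram.

    ``fraction[i]`` is the share of attractors in which area i is high;
    ``size_histogram`` maps pattern size (number of high areas) to counts.
    Empty sets yield empty outputs.
    """
    n = len(aset.names)
    if not aset.patterns:
        return {"fractions": np.zeros(n), "size_histogram": {}, "n_attractors": 0}
    P = np.array(aset.patterns)
    fractions = P.mean(axis=0)
    sizes = P.sum(axis=1)
    hist = {int(s): int((sizes == s).sum()) for s in np.unique(sizes)}
    return {"fractions": fractions, "size_histogram": hist,
            "n_attractors": len(aset.patterns)}


def sweep_attractors(connectome: Connectome, params: ModelParams,
                     mu_EE_list, g_E_self_list, candidates,
                     theta: float = 5.0, budget: int = 1 << 16,
                     mu_ratio: float = 1.67) -> np.ndarray:
    """Attractor counts over a (mu_EE, g_E_self) parameter grid.

    The long-range E-to-I strength co-scales with mu_EE at the standard
    ratio mu_IE/mu_EE = 1.67.
    """
    mu_EE_list = list(mu_EE_list)
    g_list = list(g_E_self_list)
    counts = np.zeros((len(mu_EE_list), len(g_list)), int)
    for i, mu in enumerate(mu_EE_list):
        for j, g in enumerate(g_list):
            p = params.replace(mu_EE=float(mu), mu_IE=float(mu) * mu_ratio,
                               g_E_self=float(g))
            aset = enumerate_attractors(connectome, p, candidates, theta, budget)
            counts[i, j] = aset.n_attractors
    return counts


def attractor_core_analysis(aset: AttractorSet, pattern: tuple[int, ...],
                            connectome: Connectome, params: ModelParams,
                            ratio_cutoff: float = 0.95) -> dict:
    """Single-area inhibition and restricted loop strength for one attractor.

    Re-enters the attractor via its discovery stimulus, inhibits each high
    area during the delay, and calls an area 'core' when the effect ratio on
    the remaining high areas drops below ``ratio_cutoff``. Cell type-specific
    loop strength is computed on the submatrix restricted to the high areas.
    """
    pattern = tuple(pattern)
    try:
        idx = aset.patterns.index(pattern)
    except ValueError:
        raise ValueError("pattern not present in the attractor set")
    high = np.array(pattern, bool)
    if high.sum() < 2:
        raise ValueError("need at least two high areas for a core analysis")
    members = aset.discovery_stimulus[idx]
    proto = Protocol(stimulus_targets=tuple((a, "A") for a in members),
                     I_stim=params.I_stim, T_on=params.T_on, T_off=params.T_off,
                     T_trial=params.T_trial, dt=params.dt)
    control = delay_rates(simulate(connectome, params, proto, deterministic=True))
    names = connectome.names
    effects, core = {}, {}
    for i in np.flatnonzero(high):
        mask = np.zeros(len(names), bool)
        mask[i] = True
        traj = run_inhibition(connectome, params, proto, (names[i],), "delay")
        ratio = inhibition_effect(control, delay_rates(traj), mask, aset.theta)
        effects[names[i]] = ratio
        core[names[i]] = bool(ratio < ratio_cutoff)
    restricted = loop_strength(connectome.variant("celltype"), L=2, restrict=high)
    return {"effects": effects, "core": core,
            "restricted_loop_strength": restricted, "control_rates": control}
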