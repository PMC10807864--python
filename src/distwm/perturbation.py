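"""Simulated optogenetics: phase-specific inhibition and area classification.

Inhibiting an area drives its inhibitory population with a strong current
(``I_inh``, 5 nA by default) either during the stimulus window or during the
delay (starting 2 s after stimulus offset). The effect of an inhibition run
is the ratio of the mean delay rate over *eligible* areas — persistent in
control and not themselves inhibited — to the same mean in control. Areas
are then classified as input / core / readout / nonessential from their
stimulus-phase effect, delay-phase effect and own control delay rate.

Classification runs are noise-free by default so labels cannot be flipped by
noise realizations.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .connectome import Connectome
from .params import ModelParams
from .simulator import (InhibitionEvent, Protocol, Trajectory, delay_rates,
                        persistent_areas, simulate)

__all__ = [
    "InhibitionResult",
    "run_inhibition",
    "inhibition_effect",
    "classify_areas",
    "multi_area_sweep",
    "classification_experiment",
]


@dataclass
class InhibitionResult:
    """Control vs inhibited delay rates for one inhibition run."""

    targets: tuple[str, ...]
    phase: str
    control_rates: np.ndarray
    inhibited_rates: np.ndarray
    effect_ratio: float
    excluded: list[str] = field(default_factory=list)


def run_inhibition(connectome: Connectome, params: ModelParams,
                   base_protocol: Protocol, targets, phase: str = "delay",
                   current: float | None = None, thalamus=None,
                   deterministic: bool = True, pv_mode: str = "gradient") -> Trajectory:
    """Re-run a protocol with the target areas inhibited in the given phase."""
    targets = tuple(targets)
    if not targets:
        raise ValueError("need at least one inhibition target")
    event = InhibitionEvent(areas=targets, phase=phase,
                            current=params.I_inh if current is None else current)
    proto = Protocol(stimulus_targets=base_protocol.stimulus_targets,
                     I_stim=base_protocol.I_stim, T_on=base_protocol.T_on,
                     T_off=base_protocol.T_off, T_trial=base_protocol.T_trial,
                     dt=base_protocol.dt, seed=base_protocol.seed,
                     inhibition_events=base_protocol.inhibition_events + (event,))
    return simulate(connectome, params, proto, pv_mode=pv_mode,
                    deterministic=deterministic, thalamus=thalamus)


def inhibition_effect(control_rates: np.ndarray, inhibited_rates: np.ndarray,
                      target_mask: np.ndarray, theta: float = 5.0) -> float:
    """Mean-rate ratio (inhibited / control) over eligible areas.

    Eligible areas are persistent in control (rate > theta) and not
    themselves inhibited; the inhibited areas are always excluded so the
    ratio measures the effect *on the rest of the network*.
    """
    control_rates = np.asarray(control_rates, float)
    inhibited_rates = np.asarray(inhibited_rates, float)
    target_mask = np.asarray(target_mask, bool)
    eligible = persistent_areas(control_rates, theta) & ~target_mask
    if not eligible.any():
        raise ValueError("no eligible areas: nothing persistent outside the targets")
    return float(inhibited_rates[eligible].mean() / control_rates[eligible].mean())


def classify_areas(stim_effects: np.ndarray, delay_effects: np.ndarray,
                   control_delay_rates: np.ndarray, theta_effect: float = 0.10,
                   theta_rate: float = 5.0) -> list[str]:
    """Four-way functional classification of areas.

    An effect is 'strong' when the rate decrement ``1 - ratio`` exceeds
    ``theta_effect``. Input areas have a strong stimulus-phase effect
    (assigned first); among the rest, core areas pair a strong delay-phase
    effect with high own delay rate, readout areas are high-rate but weak
    delay effect, and nonessential areas are the low-rate remainder.
    """
    stim_effects = np.asarray(stim_effects, float)
    delay_effects = np.asarray(delay_effects, float)
    rates = np.asarray(control_delay_rates, float)
    labels = []
    for s, d, r in zip(stim_effects, delay_effects, rates):
        if 1.0 - s > theta_effect:
            labels.append("input")
        elif 1.0 - d > theta_effect and r > theta_rate:
            labels.append("core")
        elif r > theta_rate:
            labels.append("readout")
        else:
            labels.append("nonessential")
    return labels


def classification_experiment(connectome: Connectome, params: ModelParams,
                              base_protocol: Protocol, theta: float = 5.0,
                              theta_effect: float = 0.10,
                              candidates=None) -> dict:
    """Single-area inhibition over both phases plus the four-way labels.

    ``candidates`` restricts which areas are individually inhibited (default:
    all areas); non-candidates keep effect ratio 1. Returns a dict with the
    control rates, per-area stimulus/delay effect ratios and labels.
    """
    control = delay_rates(simulate(connectome, params, base_protocol,
                                   deterministic=True))
    names = connectome.names
    cand = set(names if candidates is None else candidates)
    stim_eff = np.ones(len(names))
    delay_eff = np.ones(len(names))
    for i, name in enumerate(names):
        if name not in cand:
            continue
        mask = np.zeros(len(names), bool)
        mask[i] = True
        for phase, store in (("stimulus", stim_eff), ("delay", delay_eff)):
            traj = run_inhibition(connectome, params, base_protocol, (name,), phase)
            store[i] = inhibition_effect(control, delay_rates(traj), mask, theta)
    labels = classify_areas(stim_eff, delay_eff, control, theta_effect, theta)
    return {"names": names, "control_rates": control, "stim_effects": stim_eff,
            "delay_effects": delay_eff, "labels": labels}


def multi_area_sweep(connectome: Connectome, params: ModelParams,
                     base_protocol: Protocol, pool, group_size: int = 2,
                     theta: float = 5.0, max_groups: int = 256,
                     sample: int | None = None, seed: int = 0) -> dict:
    """Delay-phase inhibition of every size-k group within a pool of areas.

    Groups are enumerated in lexicographic area order; if the number of
    combinations exceeds ``max_groups``, pass ``sample`` to draw that many
    groups with the given seed instead. Each area's summary is the mean
    effect ratio over all evaluated groups containing it.

    Returns ``{'group_effects': {group: ratio}, 'per_area_mean': {...}}``.
    """
    pool = sorted(pool)
    if len(pool) < group_size:
        raise ValueError("pool smaller than group size")
    groups = list(itertools.combinations(pool, group_size))
    if len(groups) > max_groups:
        if sample is None:
            raise ValueError(
                f"{len(groups)} groups exceed max_groups={max_groups}; "
                "pass sample=N to subsample")
        rng = np.random.default_rng(seed)
        idx = rng.choice(len(groups), size=min(sample, len(groups)), replace=False)
        groups = [groups[i] for i in sorted(idx)]
    control = delay_rates(simulate(connectome, params, base_protocol,
                                   deterministic=True))
    names = connectome.names
    group_effects = {}
    for group in groups:
        mask = np.zeros(len(names), bool)
        for name in group:
            mask[names.index(name)] = True
        traj = run_inhibition(connectome, params, base_protocol, group, "delay")
        group_effects[group] = inhibition_effect(control, delay_rates(traj),
                                                 mask, theta)
    per_area = {}
    for name in pool:
        vals = [v for g, v in group_effects.items() if name in g]
        if vals:
            per_area[name] = float(np.mean(vals))
    return {"group_effects": group_effects, "per_area_mean": per_area,
            "control_rates": control}
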