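"""Model parameters and named regime presets.

All parameters are stored in SI-consistent units: seconds, nA, Hz. Values
quoted in the literature in ms or pA are converted at construction time
(e.g. the excitatory transfer-function saturation constant ``d`` = 308 ms is
stored as 0.308 s so that ``d * (a*I - b)`` is dimensionless, and the weak
cross-population coupling 10.7 pA is stored as 0.0107 nA).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import yaml

__all__ = ["ModelParams", "TCParams", "REGIMES"]


@dataclass
class TCParams:
    """Thalamocortical coupling parameters.

    The thalamus is purely excitatory (two stimulus-selective populations per
    nucleus, no recurrence, AMPA synapses). The thalamic reticular nucleus is
    folded into a constant background current ``I_th0``; its value is not a
    published constant and is calibrated so that the isolated thalamic
    baseline rate stays below 5 Hz.
    """

    g_ct: float = 0.32        # corticothalamic drive, nA
    g_E_tc: float = 0.6       # thalamocortical drive onto E populations, nA
    g_I_tc: float = 1.38      # thalamocortical drive onto the I population, nA
    I_th0: float = 0.3        # thalamic background current, nA (calibrated)
    tau_A: float = 0.002      # AMPA synaptic time constant, s
    gamma_A: float = 2.0      # AMPA gating gain


@dataclass
class ModelParams:
    """Full parameter set of the multiregional working-memory model.

    Defaults are the reference regime: local recurrent excitation is too weak
    for any isolated area to sustain persistent activity, so mnemonic states
    must be maintained by long-range loops.
    """

    # synaptic / rate time constants (s)
    tau_N: float = 0.060      # NMDA
    tau_G: float = 0.005      # GABA
    tau_A: float = 0.002      # AMPA
    tau_r: float = 0.002      # firing-rate relaxation
    tau_noise: float = 0.002  # OU noise

    # excitatory transfer function r = (aI-b)/(1-exp(-d(aI-b)))
    a: float = 140.0          # Hz/nA
    b: float = 54.0           # Hz
    d: float = 0.308          # s

    # inhibitory transfer function r = [(c1*I-c0)/g_I + r0_I]_+
    g_I: float = 4.0
    c1: float = 615.0         # Hz/nA
    c0: float = 177.0         # Hz
    r0_I: float = 5.5         # Hz

    # gating gains
    gamma: float = 1.282      # NMDA
    gamma_I: float = 2.0      # GABA

    # local circuit weights (nA)
    g_E_self: float = 0.4
    g_E_cross: float = 0.0107
    g_IE: float = 0.2656
    g_EI_0: float = 0.192
    g_EI_scaling: float = 0.83
    g_II_0: float = 0.105
    g_II_scaling: float = 0.714

    # background currents (nA)
    I0_A: float = 0.305
    I0_B: float = 0.305
    I0_C: float = 0.26

    # noise amplitudes (nA)
    sigma_A: float = 0.005
    sigma_B: float = 0.005
    sigma_C: float = 0.0

    # long-range coupling (nA)
    mu_EE: float = 0.1
    mu_IE: float = 0.167

    # connectivity shaping
    beta: float = 2.42        # CIB sigmoid steepness
    k_scale: float = 0.3      # power-law compression of weights
    alpha_h: float = 1.33     # hierarchy imputation slope
    beta_h: float = -0.22     # hierarchy imputation intercept

    # protocol defaults
    I_stim: float = 0.5       # nA
    I_inh: float = 5.0        # nA
    T_on: float = 2.0         # s
    T_off: float = 2.5        # s
    T_trial: float = 10.0     # s
    dt: float = 0.0005        # s

    # documentation-only initial-rate constant (dynamics start from zero)
    r0_E: float = 5.0         # Hz

    tc: TCParams = field(default_factory=TCParams)

    def __post_init__(self) -> None:
        for name in ("tau_N", "tau_G", "tau_A", "tau_r", "tau_noise"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.dt <= 0 or self.dt >= min(self.tau_G, self.tau_r, self.tau_noise):
            raise ValueError("dt must be positive and smaller than the fastest time constant")

    def replace(self, **kwargs) -> "ModelParams":
        """Return a copy with the given fields replaced."""
        return dataclasses.replace(self, **kwargs)

    # -- regime presets ----------------------------------------------------

    @classmethod
    def reference(cls) -> "ModelParams":
        """Weak local recurrence; persistent activity is a network effect."""
        return cls()

    @classmethod
    def alternative(cls) -> "ModelParams":
        """Strong local recurrence balanced by strong local inhibition.

        In this regime a subset of areas is bistable in isolation
        ('independent' persistent activity).
        """
        return cls(g_E_self=0.6, g_EI_0=0.5, mu_EE=0.19)

    @classmethod
    def thalamocortical(cls) -> "ModelParams":
        """Weakened cortico-cortical coupling; the thalamus closes the loop."""
        return cls(mu_EE=0.01, mu_IE=0.0167)

    @classmethod
    def attractor_sweep(cls, mu_EE: float = 0.03, g_E_self: float = 0.44) -> "ModelParams":
        """Multi-attractor census regime; mu_IE co-scales with mu_EE (ratio 1.67)."""
        return cls(mu_EE=mu_EE, mu_IE=mu_EE * 1.67, g_E_self=g_E_self)

    @classmethod
    def from_regime(cls, name: str) -> "ModelParams":
        try:
            return REGIMES[name]()
        except KeyError:
            raise ValueError(f"unknown regime {name!r}; choose from {sorted(REGIMES)}")

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_yaml(cls, path) -> "ModelParams":
        """Load parameters from a YAML file.

        The file may contain a ``regime:`` selector naming a preset; any other
        key overrides the corresponding field. A nested ``tc:`` mapping
        overrides thalamocortical fields.
        """
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        regime = data.pop("regime", None)
        base = cls.from_regime(regime) if regime else cls()
        tc_over = data.pop("tc", {})
        params = base.replace(**data) if data else base
        if tc_over:
            params = params.replace(tc=dataclasses.replace(params.tc, **tc_over))
        return params


REGIMES = {
    "reference": ModelParams.reference,
    "alternative": ModelParams.alternative,
    "thalamocortical": ModelParams.thalamocortical,
    "attractor_sweep": ModelParams.attractor_sweep,
}
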