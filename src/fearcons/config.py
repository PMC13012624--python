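"""Model configuration.

All tunable parameters of the simulator live in :class:`ModelConfig`.
Defaults reproduce the reference conditions used throughout the test
protocols; every value can be overridden programmatically or from a YAML
mapping (see :func:`ModelConfig.from_yaml`).

Units: weights are unitless synaptic strengths; thresholds are expressed in
the same units as the summed synaptic drive they gate; durations are
simulation time steps unless suffixed ``_days``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import yaml


@dataclass
class HomeostasisParams:
    """Parameters of the cubic-growth homeostasis rule applied during Sleep.

    dx/dt = r * x * (1 - x/K) * (x/A - 1)

    is bistable on x >= 0: strengths below the extinction threshold ``A``
    decay to zero (pruning), strengths above it converge to the recruitment
    strength ``K`` (consolidation).
    """

    r: float = 1.4          # learning rate, per unit homeostasis time
    A: float = 0.9          # extinction threshold (weight units), 0 < A < K
    K: float = 1.7          # recruitment strength (weight units)
    dt: float = 0.01        # Euler step in homeostasis time units
    total_time: float = 3.0  # integration time for a full-length Sleep phase
    prune_floor: float = 1e-3  # weights below this after Sleep are zeroed

    def __post_init__(self) -> None:
        if not (0 < self.A < self.K):
            raise ValueError(f"require 0 < A < K, got A={self.A}, K={self.K}")
        if self.r <= 0:
            raise ValueError(f"require r > 0, got r={self.r}")


@dataclass
class StressParams:
    """Stress-enhanced fear learning (SEFL) modulation.

    A 'traumatic' episode (US >= u_trauma for >= d_trauma consecutive steps)
    transiently boosts P-cell recruitability and lowers the homeostasis
    extinction threshold on BA_N->BA_P synapses; both relax linearly back to
    their defaults over ``recovery_days`` simulated days.
    """

    u_trauma: float = 1.0
    d_trauma: int = 10          # consecutive steps of intense US to trigger
    recruit_boost: float = 3.0  # multiplier on P-cell recruitability
    A_low: float = 0.45         # lowered extinction threshold under stress
    recovery_days: float = 5.0


@dataclass
class RecruitabilityParams:
    """Slow per-cell oscillation of plasticity eligibility (valence cells).

    Each cell alternates between a high-recruitability window of roughly
    ``high_len`` steps and a low phase several times longer, with jittered
    period and random phase so that only a small minority of cells is highly
    recruitable at any moment. Sparse single-step noise spikes let otherwise
    ineligible cells pick up weak, transient synaptic changes.
    """

    high_len: int = 200
    period_min: int = 1200
    period_max: int = 1600
    amp_min: float = 0.1      # high-window amplitude drawn per window
    amp_max: float = 1.0
    r_low: float = 0.03       # recruitability during the low phase
    spike_prob: float = 0.003  # per-cell per-step single-step noise spike


@dataclass
class ModelConfig:
    """Full parameter set of the network."""

    # --- context / sensory cortex ---
    n_features: int = 50       # categorical features per context
    n_values: int = 10         # categories per feature
    # SC has n_features * n_values one-hot units (500 by default)

    # --- hippocampus ---
    n_hip: int = 500
    hip_sparsity: float = 0.04         # 4% of cells active -> k_hip = 20
    eta_hip: float = 0.25              # recurrent Hebbian rate (fast)
    w_max_hip: float = 1.0
    hip_bg_scale: float = 0.02         # U(0, scale) background recurrent weights
    theta_hip_recall: float = 9.5      # recurrent-drive floor during Recall
    hip_day_decay: float = 0.945       # per-day multiplicative decay of
                                       # HIP recurrent and HIP-efferent weights
    recall_steps: int = 30             # convergence steps after the cue
    recall_margin: float = 0.9         # F1 >= margin counts as successful recall

    # adaptation projection (Sleep replay cycling)
    eta_adapt: float = 0.12
    adapt_decay: float = 0.999         # suppression persists across the night
    sleep_noise: float = 2.0           # s.d. of per-step drive jitter in Sleep

    # entorhinal match/mismatch gate
    theta_match: float = 0.85          # F1(EC_in, EC_out) for a context match
    ec_rel_threshold: float = 0.5      # EC_out bit on if drive >= frac * max

    # --- neocortex ---
    n_ctx: int = 500
    ctx_sparsity: float = 0.12         # denser code than HIP
    eta_ctx_percept: float = 0.002     # slow awake learning
    eta_ctx_sleep: float = 0.12        # replay-driven consolidation rate
    w_max_ctx: float = 1.0
    ctx_bg_scale: float = 0.02
    theta_ctx_recall: float = 30.0
    ctx_day_decay: float = 0.987       # half-life ~ 53 days
    theta_ctx_sleep: float = 13.0      # HIP-drive floor to reactivate CTX in Sleep
                                       # (only coherent replay consolidates)

    # cross-region plastic projections
    eta_hip_ctx: float = 0.25
    eta_hip_ban: float = 0.25
    eta_ctx_ban: float = 0.02          # strengthened only during Sleep co-replay
    eta_hip_ec: float = 0.25
    w_max_cross: float = 1.0

    # --- amygdala ---
    n_ban: int = 500                   # BA_N sized to the SC code (permutation map)
    ban_sparsity: float = 0.1          # k_ban = 50 = one cell per context feature
    eta_ban: float = 0.25              # BA_N recurrent Hebbian (error-gated)
    w_max_ban: float = 1.0
    ban_bg_scale: float = 0.0
    ban_day_decay: float = 0.995
    error_gate: float = 0.05           # minimum |prediction error| to open plasticity
    theta_ban_sleep: float = 10.0      # drive floor for BA_N co-replay
    theta_ban_recall: float = 20.0     # recurrent floor for BA_N convergence
    g_hip_ban: float = 0.1             # HIP->BA_N gain during routed Recall
    g_ctx_ban: float = 0.2             # CTX->BA_N gain during routed Recall

    n_p: int = 100                     # fear-promoting cells
    n_i: int = 100                     # fear-inhibiting cells
    eta_valence: float = 0.35          # BA_N->BA_P/I learning rate
    w_max_np: float = 2.0              # P-synapse cap: saturated afferent drive
                                       # = k_ban * w_max_np = 2x theta_p, so P-cells
                                       # reactivate from ~50% context overlap
    w_max_ni: float = 1.41             # I-synapse cap: saturated drive = ~1.18x
                                       # theta_i, so I-cells reactivate only above
                                       # ~85% overlap (extinction stays specific)
    theta_p: float = 50.0              # P activation threshold
    theta_i: float = 60.0              # I threshold (> theta_p)

    # CeA readout
    cea_gain: float = 0.3
    cea_bias: float = 10.0
    g_p: float = 1.0
    g_i: float = 1.0

    # --- sleep ---
    sleep_steps: int = 165             # default Sleep duration

    homeostasis: HomeostasisParams = field(default_factory=HomeostasisParams)
    stress: StressParams = field(default_factory=StressParams)
    recruitability: RecruitabilityParams = field(default_factory=RecruitabilityParams)

    # -------------------------------------------------- derived quantities
    @property
    def n_sc(self) -> int:
        return self.n_features * self.n_values

    @property
    def k_hip(self) -> int:
        return round(self.n_hip * self.hip_sparsity)

    @property
    def k_ctx(self) -> int:
        return round(self.n_ctx * self.ctx_sparsity)

    @property
    def k_ban(self) -> int:
        return round(self.n_ban * self.ban_sparsity)

    # -------------------------------------------------- (de)serialization
    def override(self, overrides: Mapping[str, Any]) -> "ModelConfig":
        """Return a copy with dotted-path overrides applied.

        Keys may address nested parameter groups, e.g.
        ``{"homeostasis.r": 2.8, "sleep_steps": 100}``.
        """
        cfg = dataclasses.replace(self)
        cfg.homeostasis = dataclasses.replace(self.homeostasis)
        cfg.stress = dataclasses.replace(self.stress)
        cfg.recruitability = dataclasses.replace(self.recruitability)
        for key, value in overrides.items():
            obj = cfg
            *parents, leaf = key.split(".")
            for part in parents:
                obj = getattr(obj, part)
            if not hasattr(obj, leaf):
                raise KeyError(f"unknown config parameter: {key!r}")
            setattr(obj, leaf, value)
        return cfg

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: Mapping[str, Any]) -> "ModelConfig":
        data = dict(data)
        for name, sub in (
            ("homeostasis", HomeostasisParams),
            ("stress", StressParams),
            ("recruitability", RecruitabilityParams),
        ):
            if name in data and isinstance(data[name], Mapping):
                data[name] = sub(**data[name])
        return cls(**data)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ModelConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)
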