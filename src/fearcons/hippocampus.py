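"""Hippocampal formation: sparse engrams, EC gate, recall and Sleep replay.

HIP stores context engrams as sparse (4% active) cell assemblies bound by
fast, bounded Hebbian recurrent plasticity.  During Recall a sensory cue is
applied for one step and the recurrent dynamics then run freely; activity
that fails to reach the recurrent drive floor collapses, which is how aged
(decayed) memories become irretrievable.  During Sleep, attractor dynamics
plus the fast inhibitory adaptation projection make HIP cycle spontaneously
through its stored engrams.

The entorhinal cortex is modelled as an input layer (a mirror of the SC
pattern) and an output layer driven by HIP during Recall; comparing the two
with an F1 score decides whether the retrieved memory matches the current
environment (hippocampal route) or whether recall responsibility falls to
the neocortex (cortical route).
"""

from __future__ import annotations

from enum import Enum

import numpy as np

from .config import ModelConfig
from .core import AdaptationState, Projection, hebbian_update, kwta_activate
from .metrics import f1_score


class Route(Enum):
    HIP_ROUTE = "hip"
    CTX_ROUTE = "ctx"


class HipRegion:
    """Hippocampus with EC input/output layers."""

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator):
        self.cfg = cfg
        n, n_sc = cfg.n_hip, cfg.n_sc
        self.k = cfg.k_hip
        # fixed sensory afferents: random Gaussian mixing of the SC code
        self.W_sc = Projection(
            rng.normal(0.0, 1.0, size=(n_sc, n)), plastic=False
        )
        self.W_rec = Projection(
            rng.uniform(0.0, cfg.hip_bg_scale, size=(n, n)),
            eta=cfg.eta_hip,
            w_max=cfg.w_max_hip,
        )
        np.fill_diagonal(self.W_rec.W, 0.0)
        self.W_ec_out = Projection(
            np.zeros((n, n_sc)), eta=cfg.eta_hip_ec, w_max=cfg.w_max_cross
        )
        self.adapt = AdaptationState(n, cfg.eta_adapt, cfg.adapt_decay)
        self.act = np.zeros(n, dtype=np.int8)

    # ------------------------------------------------------------ perception
    def perceive(self, sc: np.ndarray) -> np.ndarray:
        """Select the engram driven by the current context and strengthen it."""
        self.act = kwta_activate(self.W_sc.drive(sc), self.k)
        hebbian_update(self.W_rec, self.act, self.act)
        np.fill_diagonal(self.W_rec.W, 0.0)
        # bind the engram to the current EC (= SC) pattern for later playback
        hebbian_update(self.W_ec_out, self.act, sc)
        return self.act

    def cue(self, sc: np.ndarray) -> np.ndarray:
        """Apply a sensory cue for one step without plasticity."""
        self.act = kwta_activate(self.W_sc.drive(sc), self.k)
        return self.act

    # ---------------------------------------------------------------- recall
    def recall(self, cue_sc: np.ndarray, steps: int | None = None) -> np.ndarray:
        """Cue once, then converge under recurrent dynamics only.

        Units must reach the recurrent drive floor to stay active, so the
        final state is either a completed stored engram or (near-)silence.
        """
        steps = self.cfg.recall_steps if steps is None else steps
        self.cue(cue_sc)
        for _ in range(steps):
            drive = self.W_rec.drive(self.act)
            self.act = kwta_activate(drive, self.k, theta=self.cfg.theta_hip_recall)
            if not self.act.any():
                break
        return self.act

    # ----------------------------------------------------------------- sleep
    def replay_step(self, rng: np.random.Generator) -> np.ndarray:
        """One Sleep step: attractor dynamics minus adaptation, plus jitter."""
        drive = (
            self.W_rec.drive(self.act)
            - self.adapt.drive(self.act)
            + rng.normal(0.0, self.cfg.sleep_noise, size=self.cfg.n_hip)
        )
        self.act = kwta_activate(drive, self.k)
        self.adapt.step(self.act)
        return self.act

    def start_sleep(self) -> None:
        self.act = np.zeros(self.cfg.n_hip, dtype=np.int8)
        self.adapt.reset()

    # ------------------------------------------------------------------- EC
    def ec_output(self, hip_act: np.ndarray | None = None) -> np.ndarray:
        """EC output pattern driven by HIP (Recall-mode playback)."""
        act = self.act if hip_act is None else hip_act
        drive = self.W_ec_out.drive(act)
        peak = drive.max() if drive.size else 0.0
        if peak <= 1e-9:
            return np.zeros(self.cfg.n_sc, dtype=np.int8)
        return (drive >= self.cfg.ec_rel_threshold * peak).astype(np.int8)

    def day_decay(self) -> None:
        """Per-day multiplicative forgetting of HIP-held weights."""
        self.W_rec.W *= self.cfg.hip_day_decay
        self.W_ec_out.W *= self.cfg.hip_day_decay


def ec_match(
    ec_in: np.ndarray, ec_out: np.ndarray, theta_match: float
) -> tuple[float, Route]:
    """Match/mismatch gate between current input and recalled pattern.

    Returns the F1 score and the recall route it selects: the hippocampal
    route if the retrieved memory matches the environment, otherwise the
    cortical route.
    """
    f1 = f1_score(ec_in, ec_out)
    return f1, (Route.HIP_ROUTE if f1 >= theta_match else Route.CTX_ROUTE)
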