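"""Neocortex: dense, slowly learning engrams and sleep-driven consolidation.

CTX uses a denser code than HIP (12% vs 4% active by default), so engrams of
similar contexts overlap much more strongly — the substrate of the
time-dependent increase in fear generalisation once recall is handed over
from hippocampus to cortex.  Awake plasticity is weak; engrams only become
retrievable after hippocampal replay has reactivated and consolidated them
over one or more Sleep phases.  Cortical weights decay far more slowly than
hippocampal ones (half-life ~50 simulated days by default).
"""

from __future__ import annotations

import numpy as np

from .config import ModelConfig
from .core import Projection, hebbian_update, kwta_activate


class CtxRegion:
    def __init__(self, cfg: ModelConfig, rng: np.random.Generator):
        self.cfg = cfg
        n, n_sc = cfg.n_ctx, cfg.n_sc
        self.k = cfg.k_ctx
        self.W_sc = Projection(
            rng.normal(0.0, 1.0, size=(n_sc, n)), plastic=False
        )
        self.W_rec = Projection(
            rng.uniform(0.0, cfg.ctx_bg_scale, size=(n, n)),
            eta=1.0,  # rate passed per call: slow awake, faster in Sleep
            w_max=cfg.w_max_ctx,
        )
        np.fill_diagonal(self.W_rec.W, 0.0)
        self.act = np.zeros(n, dtype=np.int8)

    # ------------------------------------------------------------ perception
    def perceive(self, sc: np.ndarray) -> np.ndarray:
        """Engram cells are picked by fixed SC afferents; learning is slow."""
        self.act = kwta_activate(self.W_sc.drive(sc), self.k)
        hebbian_update(self.W_rec, self.act, self.act, self.cfg.eta_ctx_percept)
        np.fill_diagonal(self.W_rec.W, 0.0)
        return self.act

    def cue(self, sc: np.ndarray) -> np.ndarray:
        self.act = kwta_activate(self.W_sc.drive(sc), self.k)
        return self.act

    # ---------------------------------------------------------------- recall
    def recall(self, cue_sc: np.ndarray, steps: int | None = None) -> np.ndarray:
        """Same convergence contract as hippocampal recall."""
        steps = self.cfg.recall_steps if steps is None else steps
        self.cue(cue_sc)
        for _ in range(steps):
            drive = self.W_rec.drive(self.act)
            self.act = kwta_activate(drive, self.k, theta=self.cfg.theta_ctx_recall)
            if not self.act.any():
                break
        return self.act

    # ----------------------------------------------------------------- sleep
    def consolidate_step(self, hip_drive: np.ndarray) -> np.ndarray:
        """Reactivation by replayed HIP drive, then Hebbian consolidation.

        Reactivation is purely feedforward — slaved to the replayed
        hippocampal pattern — so CTX tracks whichever engram HIP currently
        replays instead of self-sustaining the previous one.  Silent
        (all-zero) when the hippocampal drive does not reach the floor: no
        update without genuine co-activity.
        """
        self.act = kwta_activate(hip_drive, self.k, theta=self.cfg.theta_ctx_sleep)
        if self.act.any():
            hebbian_update(self.W_rec, self.act, self.act, self.cfg.eta_ctx_sleep)
            np.fill_diagonal(self.W_rec.W, 0.0)
        return self.act

    def start_sleep(self) -> None:
        self.act = np.zeros(self.cfg.n_ctx, dtype=np.int8)

    def day_decay(self) -> None:
        self.W_rec.W *= self.cfg.ctx_day_decay
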