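"""The assembled network and its three operational modes.

A :class:`FearModel` wires sensory cortex, hippocampus (with EC gate),
neocortex and amygdala together and advances them through *Perception*
(stimulus-driven activation and learning), *Sleep* (hippocampal replay,
systems consolidation and synaptic homeostasis) and *Recall* (cued
retrieval without plasticity).

Canonical update order within one Perception step:
SC → EC → (HIP, CTX) → BA_N → (BA_P, BA_I) → CeA → plasticity →
recruitability/stress clocks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np

from .amygdala import BaRegion, prediction_error
from .config import ModelConfig
from .context import ContextSpec, USSchedule, blur_cue, encode_sc
from .core import Projection, hebbian_update, kwta_activate
from .cortex import CtxRegion
from .hippocampus import HipRegion, Route, ec_match
from .metrics import f1_score
from .sleep import StressState, integrate_homeostasis


@dataclass
class RecallResult:
    """Outcome of one cued Recall probe."""

    hip_act: np.ndarray
    ctx_act: np.ndarray
    ban_act: np.ndarray        # stimulus- plus route-driven amygdala state
    ban_converged: np.ndarray  # after recurrent-only convergence
    p_act: np.ndarray
    i_act: np.ndarray
    cea: float
    f1_gate: float
    route: Route

    @property
    def n_p(self) -> int:
        return int(self.p_act.sum())

    @property
    def n_i(self) -> int:
        return int(self.i_act.sum())


@dataclass
class StepRecord:
    t: int
    day: int
    mode: str
    us: float
    n_p: int
    n_i: int
    cea: float
    error: float


class FearModel:
    """Full network state: regions, cross-projections, clocks, stress."""

    def __init__(self, cfg: ModelConfig | None = None, seed: int = 0):
        self.cfg = cfg or ModelConfig()
        self.seed = seed
        self.rng = np.random.default_rng(seed)
        c = self.cfg
        self.hip = HipRegion(c, self.rng)
        self.ctx = CtxRegion(c, self.rng)
        self.ba = BaRegion(c, self.rng)
        self.W_hip_ctx = Projection(
            np.zeros((c.n_hip, c.n_ctx)), eta=c.eta_hip_ctx, w_max=c.w_max_cross
        )
        self.W_hip_ban = Projection(
            np.zeros((c.n_hip, c.n_ban)), eta=c.eta_hip_ban, w_max=c.w_max_cross
        )
        self.W_ctx_ban = Projection(
            np.zeros((c.n_ctx, c.n_ban)), eta=c.eta_ctx_ban, w_max=c.w_max_cross
        )
        self.stress = StressState(c.stress)
        self.t = 0      # global time step
        self.day = 0    # completed Perception/Sleep cycles

    # ------------------------------------------------------------ perception
    def perceive_step(self, sc: np.ndarray, us: float = 0.0) -> StepRecord:
        """One Perception-mode time step with plasticity."""
        c = self.cfg
        hip_act = self.hip.perceive(sc)
        ctx_act = self.ctx.perceive(sc)
        ban_act = self.ba.activate(self.ba.sc_drive(sc))
        p_act, i_act = self.ba.valence_state()
        cea = self.ba.cea_output(p_act, i_act)
        error = prediction_error(us, cea)
        # error-gated context-engram plasticity in the amygdala
        if self.ba.engram_update(error):
            hebbian_update(self.W_hip_ban, hip_act, ban_act)
        # valence recruitment (gated and recruitability-scaled internally)
        self.ba.valence_update(error, self.stress.recruit_boost(self.day))
        # hippocampal teaching of cortex: fast index formation
        hebbian_update(self.W_hip_ctx, hip_act, ctx_act)
        # clocks
        self.stress.observe_us(us, self.day)
        self.ba.tick_recruitability(self.rng)
        self.t += 1
        return StepRecord(self.t, self.day, "perception", us,
                          int(p_act.sum()), int(i_act.sum()), cea, error)

    def perceive_episode(
        self,
        context: ContextSpec | np.ndarray,
        us: USSchedule | float | None = None,
        steps: int | None = None,
    ) -> list[StepRecord]:
        """Present one context for an episode, with an optional US schedule."""
        sc = context if isinstance(context, np.ndarray) else encode_sc(context)
        if isinstance(us, USSchedule):
            amps = us.amplitude
        else:
            if steps is None:
                raise ValueError("steps required when us is not a USSchedule")
            amps = np.full(steps, 0.0 if us is None else float(us))
        return [self.perceive_step(sc, float(a)) for a in amps]

    # ---------------------------------------------------------------- recall
    def recall_probe(
        self,
        context: ContextSpec | np.ndarray,
        blur: float = 0.0,
        rng: np.random.Generator | None = None,
    ) -> RecallResult:
        """Cued retrieval without plasticity.

        The (optionally degraded) cue drives hippocampal and cortical
        convergence; the EC match gate selects the hippocampal or cortical
        route into BA_N.  Fear is evaluated on the stimulus- plus
        route-driven amygdala state; ``ban_converged`` additionally reports
        the attractor the BA_N engram settles into under recurrent dynamics
        alone (the memory-retrieval readout).
        """
        c = self.cfg
        rng = rng or self.rng
        sc = context if isinstance(context, np.ndarray) else encode_sc(context)
        cue = blur_cue(sc, blur, rng) if blur > 0 else sc

        hip_final = self.hip.recall(cue)
        ec_out = self.hip.ec_output(hip_final)
        f1_gate, route = ec_match(cue, ec_out, c.theta_match)
        ctx_final = self.ctx.recall(cue)

        drive = self.ba.sc_drive(cue).astype(float)
        if route is Route.HIP_ROUTE:
            drive = drive + c.g_hip_ban * self.W_hip_ban.drive(hip_final)
        else:
            drive = drive + c.g_ctx_ban * self.W_ctx_ban.drive(ctx_final)
        ban_act = self.ba.activate(drive, theta=0.5)
        p_act, i_act = self.ba.valence_state(ban_act)
        cea = self.ba.cea_output(p_act, i_act)

        conv = ban_act
        for _ in range(c.recall_steps):
            conv = kwta_activate(
                self.ba.W_rec.drive(conv), c.k_ban, theta=c.theta_ban_recall
            )
            if not conv.any():
                break
        return RecallResult(hip_final, ctx_final, ban_act, conv,
                            p_act, i_act, cea, f1_gate, route)

    # ----------------------------------------------------------------- sleep
    def run_sleep(
        self, duration: int | None = None, record: bool = False
    ) -> list[dict[str, Any]]:
        """One Sleep phase: replay-driven consolidation, then homeostasis.

        ``duration`` defaults to the configured Sleep length; shorter values
        model sleep deprivation (homeostasis integration time scales
        linearly).  Per-day weight decay and the day counter advance
        regardless of duration.
        """
        c = self.cfg
        duration = c.sleep_steps if duration is None else int(duration)
        frac = duration / c.sleep_steps if c.sleep_steps else 0.0
        trace: list[dict[str, Any]] = []

        self.hip.start_sleep()
        self.ctx.start_sleep()
        for step in range(duration):
            hip_act = self.hip.replay_step(self.rng)
            ctx_act = self.ctx.consolidate_step(self.W_hip_ctx.drive(hip_act))
            # BA_N co-replay is slaved to the hippocampal pattern; the
            # CTX->BA_N association is learned here but does not yet drive
            # activation (preventing a self-reinforcing runaway assembly)
            ban_act = self.ba.activate(
                self.W_hip_ban.drive(hip_act), theta=c.theta_ban_sleep
            )
            if ctx_act.any() and ban_act.any():
                hebbian_update(self.W_ctx_ban, ctx_act, ban_act)
            self.ba.tick_recruitability(self.rng)
            self.t += 1
            if record:
                trace.append(
                    {"step": step, "hip": hip_act.copy(),
                     "ctx": ctx_act.copy(), "ban": ban_act.copy()}
                )

        if frac > 0:
            A_p = self.stress.extinction_threshold(c.homeostasis.A, self.day)
            self.ba.W_np.W = np.minimum(
                integrate_homeostasis(self.ba.W_np.W, c.homeostasis, frac,
                                      A_override=A_p),
                c.w_max_np,
            )
            self.ba.W_ni.W = np.minimum(
                integrate_homeostasis(self.ba.W_ni.W, c.homeostasis, frac),
                c.w_max_ni,
            )
        # per-day forgetting applies with the passage of time, slept or not
        self.hip.day_decay()
        self.ctx.day_decay()
        self.ba.day_decay()
        self.W_hip_ctx.W *= c.hip_day_decay
        self.W_hip_ban.W *= c.hip_day_decay
        self.W_ctx_ban.W *= c.ctx_day_decay
        self.day += 1
        return trace

    # ------------------------------------------------------------- summaries
    def recall_success(self, result_act: np.ndarray, stored: np.ndarray) -> bool:
        """Retrieval counts as successful if F1(final, stored) >= margin."""
        return f1_score(result_act, stored) >= self.cfg.recall_margin

    def total_w_np(self) -> float:
        return float(self.ba.W_np.W.sum())

    def total_w_ni(self) -> float:
        return float(self.ba.W_ni.W.sum())

    # -------------------------------------------------------------- snapshot
    def save_state(self, path: str | Path) -> None:
        """Snapshot all weights and clocks to a single .npz container."""
        np.savez_compressed(
            path,
            hip_rec=self.hip.W_rec.W, hip_ec=self.hip.W_ec_out.W,
            hip_sc=self.hip.W_sc.W, ctx_sc=self.ctx.W_sc.W,
            ctx_rec=self.ctx.W_rec.W, ban_rec=self.ba.W_rec.W,
            w_np=self.ba.W_np.W, w_ni=self.ba.W_ni.W,
            hip_ctx=self.W_hip_ctx.W, hip_ban=self.W_hip_ban.W,
            ctx_ban=self.W_ctx_ban.W,
            clocks=np.array([self.t, self.day]),
        )

    def load_state(self, path: str | Path) -> None:
        data = np.load(path)
        self.hip.W_rec.W = data["hip_rec"]
        self.hip.W_ec_out.W = data["hip_ec"]
        self.hip.W_sc.W = data["hip_sc"]
        self.ctx.W_sc.W = data["ctx_sc"]
        self.ctx.W_rec.W = data["ctx_rec"]
        self.ba.W_rec.W = data["ban_rec"]
        self.ba.W_np.W = data["w_np"]
        self.ba.W_ni.W = data["w_ni"]
        self.W_hip_ctx.W = data["hip_ctx"]
        self.W_hip_ban.W = data["hip_ban"]
        self.W_ctx_ban.W = data["ctx_ban"]
        self.t, self.day = (int(x) for x in data["clocks"])
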