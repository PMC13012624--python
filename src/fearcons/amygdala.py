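"""Amygdala: context engrams, valence plasticity and the fear readout.

BA_N holds valence-neutral context engrams.  Its cells are selected by a
fixed one-to-one mapping from the sensory code, so the overlap between the
BA_N engrams of two contexts equals their feature overlap — the quantity the
generalisation gradients are measured against.  Recurrent BA_N plasticity
(and the hippocampal afferents binding an engram to its HIP trace) opens
only when a prediction error — the difference between the current US and
the fear output — is present.

Fear itself is carried by separate fear-promoting (P) and fear-inhibiting
(I) threshold units.  Prediction errors recruit them: positive errors
strengthen BA_N→P synapses, negative errors BA_N→I synapses, each scaled by
the postsynaptic cell's slowly oscillating *recruitability*.  Because
plasticity onto a P-cell continues for as long as an error persists, P
afferents saturate well above threshold (2x by default) and therefore
reactivate in moderately similar contexts, whereas I-cells — whose errors
vanish as soon as fear is quenched — sit just above threshold and
generalize only to highly similar contexts.  Active P/I cells excite/
inhibit the single sigmoid fear-output unit (CeA).
"""

from __future__ import annotations

import numpy as np

from .config import ModelConfig
from .core import Projection, hebbian_update, kwta_activate, sigmoid_out


def prediction_error(us: float, cea: float) -> float:
    """Signed teaching signal: US amplitude minus current fear output."""
    return float(us) - float(cea)


class Recruitability:
    """Slow per-cell square-wave eligibility with jittered periods.

    Each cell spends ``high_len`` steps per period at a window-specific high
    amplitude and the rest of the period at a low floor; initial phases are
    staggered uniformly, so the population sum stays roughly constant while
    only a small minority of cells is highly recruitable at any step.
    Sparse noise raises single cells for exactly one step.
    """

    def __init__(self, n: int, cfg: ModelConfig, rng: np.random.Generator):
        p = cfg.recruitability
        self.p = p
        self.n = n
        self.period = rng.integers(p.period_min, p.period_max + 1, size=n)
        self.offset = rng.integers(0, self.period)
        self.amp = rng.uniform(p.amp_min, p.amp_max, size=n)
        self.t = 0
        self._window_id = self._window_ids()
        self.R = self._base()

    def _window_ids(self) -> np.ndarray:
        return (self.t + self.offset) // self.period

    def _base(self) -> np.ndarray:
        in_high = (self.t + self.offset) % self.period < self.p.high_len
        return np.where(in_high, self.amp, self.p.r_low)

    def step(self, rng: np.random.Generator) -> np.ndarray:
        """Advance one global time step and return current R values."""
        self.t += 1
        wid = self._window_ids()
        renewed = wid != self._window_id
        if renewed.any():  # fresh amplitude each new high window
            self.amp[renewed] = rng.uniform(
                self.p.amp_min, self.p.amp_max, size=int(renewed.sum())
            )
            self._window_id = wid
        R = self._base()
        spikes = rng.random(self.n) < self.p.spike_prob
        if spikes.any():
            R = R.copy()
            R[spikes] = np.maximum(
                R[spikes],
                rng.uniform(self.p.amp_min, self.p.amp_max, size=int(spikes.sum())),
            )
        self.R = R
        return R


class BaRegion:
    """Basal amygdala (BA_N, BA_P, BA_I) plus the CeA readout unit."""

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator):
        self.cfg = cfg
        n, n_sc = cfg.n_ban, cfg.n_sc
        self.k = cfg.k_ban
        if n == n_sc:
            # one BA_N cell per sensory bit: engram overlap == feature overlap
            self.sc_map = rng.permutation(n_sc)
            self.W_sc = None
        else:
            self.sc_map = None
            self.W_sc = Projection(rng.normal(0.0, 1.0, size=(n_sc, n)), plastic=False)
        self.W_rec = Projection(
            rng.uniform(0.0, cfg.ban_bg_scale, size=(n, n)) if cfg.ban_bg_scale
            else np.zeros((n, n)),
            eta=cfg.eta_ban,
            w_max=cfg.w_max_ban,
        )
        self.W_np = Projection(
            np.zeros((n, cfg.n_p)), eta=cfg.eta_valence, w_max=cfg.w_max_np
        )
        self.W_ni = Projection(
            np.zeros((n, cfg.n_i)), eta=cfg.eta_valence, w_max=cfg.w_max_ni
        )
        self.rec_p = Recruitability(cfg.n_p, cfg, rng)
        self.rec_i = Recruitability(cfg.n_i, cfg, rng)
        self.act = np.zeros(n, dtype=np.int8)

    # ----------------------------------------------------------- activation
    def sc_drive(self, sc: np.ndarray) -> np.ndarray:
        if self.sc_map is not None:
            return np.asarray(sc, dtype=float)[self.sc_map]
        return self.W_sc.drive(sc)

    def activate(self, drive: np.ndarray, theta: float = 0.5) -> np.ndarray:
        self.act = kwta_activate(drive, self.k, theta=theta)
        return self.act

    def valence_state(
        self, ban_act: np.ndarray | None = None
    ) -> tuple[np.ndarray, np.ndarray]:
        """Binary P- and I-cell activations for the given BA_N pattern."""
        act = self.act if ban_act is None else ban_act
        p_act = (self.W_np.drive(act) >= self.cfg.theta_p).astype(np.int8)
        i_act = (self.W_ni.drive(act) >= self.cfg.theta_i).astype(np.int8)
        return p_act, i_act

    def cea_output(self, p_act: np.ndarray, i_act: np.ndarray) -> float:
        """Sigmoid fear readout; clipped to zero when no P-cell is active."""
        if p_act.sum() == 0:
            return 0.0
        net = self.cfg.g_p * float(p_act.sum()) - self.cfg.g_i * float(i_act.sum())
        return sigmoid_out(net, self.cfg.cea_gain, self.cfg.cea_bias)

    # ------------------------------------------------------------ plasticity
    def engram_update(self, error: float) -> bool:
        """Error-gated recurrent Hebbian step on the active BA_N engram."""
        if abs(error) <= self.cfg.error_gate:
            return False
        hebbian_update(self.W_rec, self.act, self.act)
        np.fill_diagonal(self.W_rec.W, 0.0)
        return True

    def valence_update(
        self, error: float, recruit_boost: float = 1.0
    ) -> None:
        """Recruit P-cells on positive, I-cells on negative prediction error.

        The per-cell step is eta * |error| * R, capped at w_max; under acute
        stress the P-cell recruitability is multiplied by ``recruit_boost``.
        """
        idx = np.flatnonzero(self.act)
        if idx.size == 0 or abs(error) <= self.cfg.error_gate:
            return
        if error > 0:
            R = np.minimum(1.0, self.rec_p.R * recruit_boost)
            W, proj = self.W_np.W, self.W_np
            delta = proj.eta * error * R
        else:
            R = self.rec_i.R
            W, proj = self.W_ni.W, self.W_ni
            delta = proj.eta * (-error) * R
        block = W[idx, :]
        np.minimum(block + delta[None, :], proj.w_max, out=block)
        W[idx, :] = block

    def tick_recruitability(self, rng: np.random.Generator) -> None:
        self.rec_p.step(rng)
        self.rec_i.step(rng)

    def day_decay(self) -> None:
        self.W_rec.W *= self.cfg.ban_day_decay
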