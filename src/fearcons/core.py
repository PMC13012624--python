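"""Shared network primitives.

Binary k-winner-take-all layers, bounded Hebbian plasticity, the fast
inhibitory 'adaptation projection' that forces replay to cycle between
attractors, and the single-unit sigmoid used by the fear-output neuron.

The recurrent learning rule is potentiation-only with a hard per-synapse
cap: synaptic weakening happens exclusively through slow per-day decay
(forgetting) and through sleep homeostasis on valence synapses.  A strategy
hook (`hebbian_update` operating on any plastic `Projection`) keeps the rule
swappable for a probability-trace (BCPNN-style) variant without touching the
region code.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


def kwta_activate(
    drive: np.ndarray, k: int, theta: float = -np.inf
) -> np.ndarray:
    """Binary k-winner-take-all activation.

    The ``k`` units with the largest drive — among those whose drive reaches
    the floor ``theta`` — become active.  Fewer than ``k`` may activate if
    fewer pass the floor.  Ties are broken deterministically in favour of the
    lowest unit index.
    """
    drive = np.asarray(drive, dtype=float)
    if k < 0:
        raise ValueError("k must be non-negative")
    if k > drive.size:
        raise ValueError(f"k={k} exceeds layer size {drive.size}")
    act = np.zeros(drive.size, dtype=np.int8)
    if k == 0:
        return act
    eligible = np.flatnonzero(drive >= theta)
    if eligible.size == 0:
        return act
    if eligible.size <= k:
        act[eligible] = 1
        return act
    # stable sort on -drive keeps lowest-index-first among ties
    order = eligible[np.argsort(-drive[eligible], kind="stable")]
    act[order[:k]] = 1
    return act


def sigmoid_out(net: float, gain: float, bias: float) -> float:
    """Logistic readout 1 / (1 + exp(-gain * (net - bias)))."""
    from scipy.special import expit

    return float(expit(gain * (net - bias)))


@dataclass
class Projection:
    """A weight matrix (pre x post) with learning metadata.

    ``plastic=False`` projections are structural and must never change after
    construction; plastic excitatory projections are bounded in [0, w_max].
    """

    W: np.ndarray
    eta: float = 0.0
    w_max: float = 1.0
    plastic: bool = True
    sign: int = +1  # +1 excitatory, -1 inhibitory

    def copy(self) -> "Projection":
        return Projection(self.W.copy(), self.eta, self.w_max, self.plastic, self.sign)

    def drive(self, pre_act: np.ndarray) -> np.ndarray:
        """Post-synaptic drive for a binary presynaptic activity vector."""
        return self.sign * (self.W.T @ pre_act)


def hebbian_update(
    proj: Projection,
    pre: np.ndarray,
    post: np.ndarray,
    rate_scale: float = 1.0,
) -> None:
    """Bounded potentiation-only Hebbian step on co-active (pre, post) pairs.

    W_ij <- min(w_max, W_ij + eta * rate_scale) for pre_i = post_j = 1.
    No LTD: entries of non-co-active pairs are untouched.
    """
    if not proj.plastic:
        raise ValueError("hebbian_update called on a non-plastic projection")
    if rate_scale < 0:
        raise ValueError("rate_scale must be non-negative")
    if rate_scale == 0.0:
        return
    pre_idx = np.flatnonzero(pre)
    post_idx = np.flatnonzero(post)
    if pre_idx.size == 0 or post_idx.size == 0:
        return
    block = proj.W[np.ix_(pre_idx, post_idx)]
    np.minimum(block + proj.eta * rate_scale, proj.w_max, out=block)
    proj.W[np.ix_(pre_idx, post_idx)] = block


@dataclass
class AdaptationState:
    """Fast inhibitory Hebbian weights among one region's units.

    Co-active pairs are rapidly strengthened each Sleep step, suppressing the
    currently replayed engram so the attractor dynamics move on; all entries
    decay multiplicatively toward zero.
    """

    n: int
    eta_adapt: float = 0.12
    decay: float = 0.995
    A_inh: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.A_inh is None:
            self.A_inh = np.zeros((self.n, self.n))

    def step(self, act: np.ndarray) -> None:
        """One Sleep-mode update: decay, then strengthen co-active pairs."""
        self.A_inh *= self.decay
        idx = np.flatnonzero(act)
        if idx.size:
            self.A_inh[np.ix_(idx, idx)] += self.eta_adapt

    def drive(self, act: np.ndarray) -> np.ndarray:
        return self.A_inh.T @ act

    def reset(self) -> None:
        self.A_inh[:] = 0.0
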