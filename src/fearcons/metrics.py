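"""Summary metrics on binary activity patterns and projections."""

from __future__ import annotations

import numpy as np

from .core import Projection


def f1_score(a: np.ndarray, b: np.ndarray) -> float:
    """Set-overlap F1 between two binary patterns: 2|A∩B| / (|A|+|B|).

    Defined as 0 when both patterns are empty.
    """
    a = np.asarray(a).astype(bool)
    b = np.asarray(b).astype(bool)
    if a.shape != b.shape:
        raise ValueError("patterns have mismatched geometry")
    denom = a.sum() + b.sum()
    if denom == 0:
        return 0.0
    return float(2.0 * np.logical_and(a, b).sum() / denom)


def pattern_distance(act: np.ndarray, stored: np.ndarray) -> float:
    """Normalized distance between active sets: 1 − Jaccard index.

    0 iff the active sets are identical, 1 for disjoint non-empty sets.
    Two empty sets are at distance 0.
    """
    act = np.asarray(act).astype(bool)
    stored = np.asarray(stored).astype(bool)
    if act.shape != stored.shape:
        raise ValueError("patterns have mismatched geometry")
    union = np.logical_or(act, stored).sum()
    if union == 0:
        return 0.0
    return float(1.0 - np.logical_and(act, stored).sum() / union)


def encoding_strength(proj: Projection, engram: np.ndarray) -> float:
    """Within-engram weight mass over total outgoing mass of engram cells.

    ``engram`` is a binary vector (or index set) over the presynaptic layer
    of a recurrent projection.  Returns a value in [0, 1]; 0 for an empty
    engram or an all-zero weight matrix.
    """
    engram = np.asarray(engram)
    idx = np.flatnonzero(engram) if engram.dtype != np.intp else engram
    if idx.size == 0:
        return 0.0
    outgoing = proj.W[idx, :].sum()
    if outgoing == 0:
        return 0.0
    within = proj.W[np.ix_(idx, idx)].sum()
    return float(within / outgoing)
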