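"""Context generation and sensory encoding.

A *context* (an environment the simulated animal can be placed in) is a
vector of ``F`` categorical features, each taking one of ``V`` values.  The
sensory cortex represents a context as a binary one-hot block code of
``F * V`` units, so that the number of shared active SC bits between two
contexts is exactly proportional to the number of shared features.  Families
of similar contexts are produced by fixing a random fraction of the features
of a base context and independently resampling the remainder; chance matches
in the resampled features are permitted, so the realized overlap slightly
exceeds the nominal one on average.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

F_DEFAULT = 50
V_DEFAULT = 10


@dataclass(frozen=True)
class ContextSpec:
    """A context: ``F`` categorical features with values in ``{0..V-1}``."""

    features: np.ndarray
    n_values: int = V_DEFAULT

    def __post_init__(self) -> None:
        feats = np.asarray(self.features, dtype=np.int64)
        if feats.ndim != 1:
            raise ValueError("features must be a 1-D integer vector")
        if feats.size and (feats.min() < 0 or feats.max() >= self.n_values):
            raise ValueError(f"feature values must lie in 0..{self.n_values - 1}")
        object.__setattr__(self, "features", feats)

    @property
    def n_features(self) -> int:
        return int(self.features.size)

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, ContextSpec)
            and self.n_values == other.n_values
            and np.array_equal(self.features, other.features)
        )

    def __hash__(self) -> int:
        return hash((self.n_values, self.features.tobytes()))

    # ---------------------------------------------------------- serialization
    def to_json(self) -> str:
        return json.dumps(
            {"features": self.features.tolist(), "n_values": self.n_values}
        )

    @classmethod
    def from_json(cls, payload: str) -> "ContextSpec":
        data = json.loads(payload)
        return cls(np.asarray(data["features"], dtype=np.int64), data["n_values"])


@dataclass(frozen=True)
class USSchedule:
    """Per-step aversive-stimulus amplitudes accompanying one episode."""

    amplitude: np.ndarray

    def __post_init__(self) -> None:
        amp = np.asarray(self.amplitude, dtype=float)
        if amp.ndim != 1:
            raise ValueError("amplitude must be a 1-D vector")
        if amp.size and amp.min() < 0:
            raise ValueError("US amplitudes must be non-negative")
        object.__setattr__(self, "amplitude", amp)

    @property
    def steps(self) -> int:
        return int(self.amplitude.size)

    @classmethod
    def constant(cls, steps: int, amplitude: float) -> "USSchedule":
        return cls(np.full(steps, float(amplitude)))

    @classmethod
    def none(cls, steps: int) -> "USSchedule":
        return cls(np.zeros(steps))

    @classmethod
    def window(
        cls, steps: int, amplitude: float, start: int = 0, end: int | None = None
    ) -> "USSchedule":
        """US of given amplitude on steps ``start:end``, zero elsewhere."""
        amp = np.zeros(steps)
        amp[start : steps if end is None else end] = amplitude
        return cls(amp)

    def to_json(self) -> str:
        return json.dumps({"amplitude": self.amplitude.tolist()})

    @classmethod
    def from_json(cls, payload: str) -> "USSchedule":
        return cls(np.asarray(json.loads(payload)["amplitude"], dtype=float))


# ------------------------------------------------------------------ sampling

def sample_context(
    rng: np.random.Generator, n_features: int = F_DEFAULT, n_values: int = V_DEFAULT
) -> ContextSpec:
    """Draw a context with independent, uniform categorical features."""
    return ContextSpec(rng.integers(0, n_values, size=n_features), n_values)


def make_similar(
    base: ContextSpec, overlap: float, rng: np.random.Generator
) -> ContextSpec:
    """A variant of ``base`` sharing a controlled fraction of its features.

    ``round(overlap * F)`` randomly chosen features are copied from the base;
    the rest are resampled uniformly (chance matches allowed), so the
    expected realized overlap is ``overlap + (1 - overlap) / V``.
    """
    if not 0.0 <= overlap <= 1.0:
        raise ValueError(f"overlap must lie in [0, 1], got {overlap}")
    F = base.n_features
    n_fixed = round(overlap * F)
    fixed = rng.choice(F, size=n_fixed, replace=False)
    features = rng.integers(0, base.n_values, size=F)
    features[fixed] = base.features[fixed]
    return ContextSpec(features, base.n_values)


def overlap_fraction(a: ContextSpec, b: ContextSpec) -> float:
    """Fraction of features on which two contexts agree."""
    if a.n_features != b.n_features or a.n_values != b.n_values:
        raise ValueError("contexts have mismatched geometry")
    return float(np.mean(a.features == b.features))


# ------------------------------------------------------------------ encoding

def encode_sc(context: ContextSpec) -> np.ndarray:
    """One-hot block encoding: bit ``f * V + features[f]`` set per feature."""
    bits = np.zeros(context.n_features * context.n_values, dtype=np.int8)
    bits[np.arange(context.n_features) * context.n_values + context.features] = 1
    return bits


def decode_sc(bits: np.ndarray, n_values: int = V_DEFAULT) -> ContextSpec:
    """Inverse of :func:`encode_sc` (block argmax; requires one bit per block)."""
    blocks = np.asarray(bits).reshape(-1, n_values)
    if not np.all(blocks.sum(axis=1) == 1):
        raise ValueError("not a valid one-hot block pattern")
    return ContextSpec(blocks.argmax(axis=1), n_values)


def blur_cue(
    pattern: np.ndarray, mask_frac: float, rng: np.random.Generator
) -> np.ndarray:
    """Randomly clear a fraction of the set bits of an SC pattern.

    Masking only removes information — no spurious bits are introduced.
    """
    if not 0.0 <= mask_frac <= 1.0:
        raise ValueError(f"mask_frac must lie in [0, 1], got {mask_frac}")
    out = np.array(pattern, dtype=np.int8, copy=True)
    on = np.flatnonzero(out)
    n_clear = round(mask_frac * on.size)
    if n_clear:
        out[rng.choice(on, size=n_clear, replace=False)] = 0
    return out
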