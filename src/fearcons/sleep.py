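"""Sleep-phase machinery: synaptic homeostasis and stress modulation.

Homeostasis acts only on the valence-coding synapses (BA_N→BA_P and
BA_N→BA_I).  Each weight evolves under the cubic growth rule

    dx/dt = r * x * (1 - x/K) * (x/A - 1)

which is bistable on x >= 0: 0 and the recruitment strength K are stable
fixed points, the extinction threshold A an unstable one.  Overnight, weak
or incidentally strengthened synapses (x < A) are pruned toward zero while
committed synapses (x > A) are normalized toward K — stronger-than-needed
synapses are pulled *down* to K, weaker committed ones pulled up.  The
integration time is proportional to the Sleep duration, so curtailed sleep
performs only a partial renormalization.

Acute stress (a sufficiently long, sufficiently intense aversive episode)
transiently boosts P-cell recruitability and lowers the extinction threshold
on BA_N→BA_P synapses; both effects relax linearly over ~5 simulated days.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import HomeostasisParams, StressParams


def homeostasis_rhs(x: np.ndarray | float, p: HomeostasisParams) -> np.ndarray | float:
    """Cubic growth rate of change for synaptic strength x >= 0."""
    return p.r * x * (1.0 - x / p.K) * (x / p.A - 1.0)


def integrate_homeostasis(
    w: np.ndarray,
    p: HomeostasisParams,
    sleep_frac: float = 1.0,
    A_override: float | None = None,
) -> np.ndarray:
    """Integrate the homeostasis ODE for every weight (explicit Euler).

    ``sleep_frac`` scales the integration time linearly with Sleep duration
    (1.0 = a full-length Sleep phase); ``A_override`` substitutes a lowered
    extinction threshold (stress).  Weights below the pruning floor at the
    end are zeroed.  Zero weights are fixed points and skipped.
    """
    if sleep_frac <= 0.0:
        return np.asarray(w, dtype=float).copy()
    r, K = p.r, p.K
    A = p.A if A_override is None else A_override
    out = np.asarray(w, dtype=float).copy()
    mask = out > 0
    x = out[mask]
    total = p.total_time * sleep_frac
    n_steps = max(1, int(round(total / p.dt)))
    dt = total / n_steps
    for _ in range(n_steps):
        x += dt * (r * x * (1.0 - x / K) * (x / A - 1.0))
        np.maximum(x, 0.0, out=x)
    x[x < p.prune_floor] = 0.0
    out[mask] = x
    return out


@dataclass
class StressState:
    """Tracks trauma exposure and the decaying parameter modulation."""

    params: StressParams
    active: bool = False
    onset_day: float = -np.inf
    _streak: int = field(default=0, repr=False)

    def observe_us(self, us: float, day: float) -> None:
        """Per-step trauma detector: prolonged, intense US triggers stress."""
        if us >= self.params.u_trauma:
            self._streak += 1
            if self._streak >= self.params.d_trauma:
                self.active = True
                self.onset_day = day  # re-triggering refreshes the onset
        else:
            self._streak = 0

    def severity(self, day: float) -> float:
        """Modulation strength in [0, 1]; linear recovery over ~5 days."""
        if not self.active:
            return 0.0
        s = 1.0 - (day - self.onset_day) / self.params.recovery_days
        return float(np.clip(s, 0.0, 1.0))

    def recruit_boost(self, day: float) -> float:
        return 1.0 + (self.params.recruit_boost - 1.0) * self.severity(day)

    def extinction_threshold(self, default_A: float, day: float) -> float:
        """Effective homeostasis threshold for BA_N→BA_P synapses."""
        return default_A - (default_A - self.params.A_low) * self.severity(day)
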