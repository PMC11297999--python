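"""Detection of well-to-well transitions and waiting-time statistics.

A transition is a crossing of the separatrix (midpoint between two
adjacent metastable centers along a chosen dimension) after which the
trajectory stays on the new side for a minimum number of steps — the
persistence rule that filters out brief barrier flickers.  Waiting
times are the intervals between consecutive recorded transitions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import ks_2samp

from .timeseries import TimeSeries

__all__ = [
    "TransitionRecord",
    "TransitionStats",
    "detect_transitions",
    "count_in_window",
    "compare_waiting_times",
    "first_persistent_crossing",
]

#: default persistence requirement, in sampling steps
DEFAULT_PERSISTENCE = 50


@dataclass(frozen=True)
class TransitionRecord:
    step: int
    time: float
    from_state: int
    to_state: int


@dataclass
class TransitionStats:
    transitions: list[TransitionRecord] = field(default_factory=list)
    dt: float = 1.0

    @property
    def count(self) -> int:
        return len(self.transitions)

    @property
    def waiting_times(self) -> np.ndarray:
        times = np.array([rec.time for rec in self.transitions])
        return np.diff(times)

    @property
    def directional_counts(self) -> dict[tuple[int, int], int]:
        out: dict[tuple[int, int], int] = {}
        for rec in self.transitions:
            key = (rec.from_state, rec.to_state)
            out[key] = out.get(key, 0) + 1
        return out

    def summary(self) -> dict:
        wt = self.waiting_times
        return {
            "count": self.count,
            "mean_waiting_time": float(wt.mean()) if wt.size else None,
            "median_waiting_time": float(np.median(wt)) if wt.size else None,
            "directional_counts": {
                f"{a}->{b}": n for (a, b), n in self.directional_counts.items()
            },
        }


def _persistent_crossings(x: np.ndarray, thresholds: np.ndarray, persistence: int):
    """Yield (step, old_level, new_level) for persistent threshold crossings.

    Levels are indices into the sorted center list; the current level
    starts from the side of the first sample and changes only when the
    signal sits on a new side of the corresponding separatrix for at
    least ``persistence`` consecutive steps.
    """
    lv = np.searchsorted(thresholds, x)
    level = int(lv[0])
    n = x.size
    i = 1
    while i < n:
        if lv[i] != level:
            end = i + persistence
            if end <= n and np.all(lv[i:end] != level):
                # persistent departure from the old level; settle on the
                # level held at the end of the persistence window
                settled = int(lv[end - 1])
                yield i, level, settled
                level = settled
        i += 1


def detect_transitions(
    series: TimeSeries,
    centers,
    dim: int = 0,
    persistence: int = DEFAULT_PERSISTENCE,
) -> TransitionStats:
    """Record persistent separatrix crossings along one dimension.

    ``centers`` may be a :class:`~multiscale_rc.tuning.StableStates`
    instance or a plain array of center coordinates; they are projected
    onto dimension ``dim`` and sorted, and each adjacent pair defines a
    separatrix at its midpoint.
    """
    vals = np.asarray(getattr(centers, "centers", centers), dtype=float)
    vals = np.atleast_2d(vals)
    levels = np.sort(vals[:, dim] if vals.shape[1] > dim else vals.ravel())
    if levels.size < 2:
        raise ValueError("transition detection needs at least two centers")
    if persistence < 1:
        raise ValueError("persistence must be >= 1")
    thresholds = 0.5 * (levels[:-1] + levels[1:])
    x = series.column(dim)
    stats = TransitionStats(dt=series.dt)
    for step, old, new in _persistent_crossings(x, thresholds, persistence):
        # a jump over several separatrices decomposes into adjacent-pair records
        direction = 1 if new > old else -1
        for a in range(old, new, direction):
            stats.transitions.append(
                TransitionRecord(
                    step=step,
                    time=series.t0 + step * series.dt,
                    from_state=a,
                    to_state=a + direction,
                )
            )
    return stats


def first_persistent_crossing(
    x: np.ndarray,
    threshold: float = 0.0,
    persistence: int = DEFAULT_PERSISTENCE,
) -> int | None:
    """Index of the first upward crossing that persists, or None.

    The signal must sit at or below the threshold at some point, then
    stay strictly above it for ``persistence`` consecutive steps.
    """
    above = x > threshold
    for i in range(1, x.size - persistence + 1):
        if above[i] and not above[i - 1] and np.all(above[i:i + persistence]):
            return i
    return None


def count_in_window(stats: TransitionStats, window: tuple[float, float]) -> int:
    """Number of transitions with time in the half-open window [t_a, t_b)."""
    t_a, t_b = window
    if not t_a < t_b:
        raise ValueError("window must satisfy t_a < t_b")
    return sum(1 for rec in stats.transitions if t_a <= rec.time < t_b)


def compare_waiting_times(a, b) -> dict[str, float]:
    """Two-sample KS statistic and mean ratio between waiting-time pools."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both waiting-time samples must be nonempty")
    ks = ks_2samp(a, b)
    return {"ks_statistic": float(ks.statistic), "mean_ratio": float(a.mean() / b.mean())}
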