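"""Sampling-time grids for minute-scale expression time courses.

A time course is described by the minutes at which samples were lysed.
The two reference designs are a 4-minute grid over 0..600 min (151 nominal
times, of which six failed quality control in the original mouse
experiment) and a 10-minute grid over 0..600 min (61 times, human).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["TimeGrid", "make_time_grid", "MOUSE_DROPPED_MINUTES", "mouse_grid", "human_grid"]

#: Nominal mouse sampling times removed by sequencing quality control.
MOUSE_DROPPED_MINUTES = frozenset({60, 132, 452, 464, 492, 512})


@dataclass(frozen=True)
class TimeGrid:
    """Strictly increasing sampling times (minutes) with nominal spacing.

    ``interval`` is the design spacing in minutes; ``dropped`` records
    nominal times removed from the design (e.g. failed samples). The
    ``times`` actually present need not be evenly spaced once samples have
    been dropped or the grid subsampled.
    """

    times: np.ndarray
    interval: float
    dropped: frozenset = field(default_factory=frozenset)

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        if t.ndim != 1 or t.size < 2:
            raise ValueError("a time grid needs at least two sampling times")
        if np.any(np.diff(t) <= 0):
            raise ValueError("sampling times must be strictly increasing")
        if np.any(t < 0):
            raise ValueError("sampling times must be nonnegative")
        object.__setattr__(self, "times", t)

    def __len__(self) -> int:
        return self.times.size

    @property
    def span(self) -> float:
        return float(self.times[-1] - self.times[0])

    def sample_ids(self) -> list[str]:
        """Column labels encoding time in minutes, e.g. ``t0004``."""
        return [f"t{int(round(t)):04d}" for t in self.times]


def make_time_grid(interval: float, end: float, dropped=()) -> TimeGrid:
    """Build the nominal grid 0, interval, 2*interval, ..., end minus drops.

    ``dropped`` times must lie on the nominal grid; ``interval`` must
    divide ``end`` exactly.
    """
    if interval <= 0:
        raise ValueError("interval must be positive")
    n_steps = end / interval
    if abs(n_steps - round(n_steps)) > 1e-9:
        raise ValueError(f"interval {interval} does not divide end {end}")
    nominal = np.arange(0, int(round(n_steps)) + 1, dtype=float) * interval
    dropped = frozenset(float(d) for d in dropped)
    nominal_set = set(nominal.tolist())
    bad = sorted(d for d in dropped if d not in nominal_set)
    if bad:
        raise ValueError(f"dropped times not on the nominal grid: {bad}")
    keep = np.array([t for t in nominal if t not in dropped])
    return TimeGrid(times=keep, interval=float(interval), dropped=dropped)


def mouse_grid() -> TimeGrid:
    """The 4-minute, 145-sample design (six nominal times dropped)."""
    return make_time_grid(4, 600, MOUSE_DROPPED_MINUTES)


def human_grid() -> TimeGrid:
    """The 10-minute, 61-sample design."""
    return make_time_grid(10, 600)
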