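"""Pattern taxonomy over fitted direction sequences.

The direction sequence of a gene's segmented fit (up / down / same per
segment) maps onto a fixed taxonomy:

    monotonic up:   up                 monotonic down: down
    peak:           up-down, up-same-down
    delayed peak:   same-up-down, same-up-same-down
    dip:            down-up, down-same-up
    delayed dip:    same-down-up, same-down-same-up
    delayed up:     same-up            delayed down:   same-down
    immediate on:   up-same            immediate off:  down-same
    cyclic:         anything else with at least two disconnected up or
                    down runs (e.g. up-down-up, up-down-down-up,
                    up-same-down-up)

Genes failing the adjusted-R^2 gate are "not dynamic" regardless of their
direction sequence. Onset is immediate when the first segment moves,
delayed when a flat segment precedes the first movement, none otherwise.

Two conventions cover sequences the rule table leaves open: adjacent
segments with the same direction are merged into one run before matching
(so up-down-down reads as up-down, a peak), and a trailing flat run that
prevents a match is ignored on a second pass (so up-same-down-same is
still a peak, while up-same keeps its own label, immediate on). A fully
delayed plateau (same-up-same) counts as delayed up, and symmetrically
for delayed down.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .trendfit import DOWN, SAME, UP, SegmentedFit

__all__ = [
    "PatternLabel",
    "PeakCall",
    "pattern_label",
    "detect_peaks",
    "onset_class",
    "first_breakpoint",
    "breakpoint_census",
    "pattern_table",
    "PATTERN_LABELS",
]

PATTERN_LABELS = (
    "not_dynamic",
    "monotonic_up",
    "monotonic_down",
    "peak",
    "delayed_peak",
    "dip",
    "delayed_dip",
    "delayed_up",
    "delayed_down",
    "immediate_on",
    "immediate_off",
    "cyclic",
)


@dataclass(frozen=True)
class PatternLabel:
    label: str
    onset: str  # immediate | delayed | none


@dataclass(frozen=True)
class PeakCall:
    peak_time: float
    up_slope: float
    down_slope: float
    rank: int  # 1 = first peak in time


def _runs(directions):
    """Collapse adjacent equal directions into (direction, [segment idx]) runs."""
    runs = []
    for i, d in enumerate(directions):
        if d not in (UP, DOWN, SAME):
            raise ValueError(f"unknown direction symbol {d!r}")
        if runs and runs[-1][0] == d:
            runs[-1][1].append(i)
        else:
            runs.append((d, [i]))
    return runs


_CORE_TABLE = {
    (UP,): ("monotonic_up", "delayed_up"),
    (DOWN,): ("monotonic_down", "delayed_down"),
    (UP, DOWN): ("peak", "delayed_peak"),
    (UP, SAME, DOWN): ("peak", "delayed_peak"),
    (DOWN, UP): ("dip", "delayed_dip"),
    (DOWN, SAME, UP): ("dip", "delayed_dip"),
    (UP, SAME): ("immediate_on", "delayed_up"),
    (DOWN, SAME): ("immediate_off", "delayed_down"),
}


def pattern_label(directions, K: int | None = None, dynamic: bool = True) -> PatternLabel:
    """Classify a direction sequence; ``dynamic=False`` forces not_dynamic."""
    if K is not None and len(directions) != K + 1:
        raise ValueError("directions length must equal K + 1")
    if not dynamic:
        return PatternLabel("not_dynamic", "none")
    runs = _runs(directions)
    seq = tuple(d for d, _ in runs)
    if not any(d in (UP, DOWN) for d in seq):
        return PatternLabel("not_dynamic", "none")
    delayed = seq[0] == SAME
    core = seq[1:] if delayed else seq
    onset = "delayed" if delayed else "immediate"

    hit = _CORE_TABLE.get(core)
    if hit is None and core and core[-1] == SAME:
        hit = _CORE_TABLE.get(core[:-1])  # ignore a trailing plateau
    if hit is not None:
        return PatternLabel(hit[1] if delayed else hit[0], onset)
    # residual: two or more disconnected up/down excursions
    return PatternLabel("cyclic", onset)


def onset_class(fit: SegmentedFit) -> str:
    """immediate | delayed | none from the first segment's direction."""
    dirs = fit.directions
    if not any(d in (UP, DOWN) for d in dirs):
        return "none"
    return "delayed" if dirs[0] == SAME else "immediate"


def first_breakpoint(fit: SegmentedFit) -> float | None:
    """Time of the first breakpoint; None for monotonic fits (K = 0)."""
    if fit.K == 0:
        return None
    return float(fit.breakpoints[0])


def detect_peaks(fit: SegmentedFit) -> list[PeakCall]:
    """Peaks: an up run followed, optionally through one flat run, by a
    down run. The peak time is the breakpoint ending the up run; slopes
    are taken from the segments flanking that breakpoint (last segment of
    the up run, first of the down run)."""
    runs = _runs(fit.directions)
    peaks: list[PeakCall] = []
    i = 0
    while i < len(runs):
        d, segs = runs[i]
        if d == UP:
            j = i + 1
            if j < len(runs) and runs[j][0] == SAME:
                j += 1
            if j < len(runs) and runs[j][0] == DOWN:
                up_seg = segs[-1]
                down_seg = runs[j][1][0]
                peaks.append(
                    PeakCall(
                        peak_time=float(fit.breakpoints[up_seg]),
                        up_slope=float(fit.slopes[up_seg]),
                        down_slope=float(fit.slopes[down_seg]),
                        rank=len(peaks) + 1,
                    )
                )
                i = j
                continue
        i += 1
    return peaks


def breakpoint_census(fits, cutpoints) -> pd.DataFrame:
    """Count breakpoints (and genes with >= 1 breakpoint) before each
    cutpoint, over dynamic genes only. A gene with several breakpoints in
    a window contributes each of them to the breakpoint count but once to
    the gene count."""
    cutpoints = list(cutpoints)
    rows = []
    fits = list(fits)
    for c in cutpoints:
        n_bp = 0
        n_genes = 0
        for fit in fits:
            if not fit.dynamic:
                continue
            k = int(np.sum(fit.breakpoints < c))
            n_bp += k
            n_genes += k > 0
        rows.append({"cutpoint": c, "n_breakpoints": n_bp, "n_genes": n_genes})
    return pd.DataFrame(rows)


def pattern_table(fits: dict[str, SegmentedFit]) -> pd.DataFrame:
    """Per-gene pattern summary: label, onset, K, first breakpoint and the
    first peak's time and flanking slopes."""
    rows = []
    for gene, fit in fits.items():
        lab = pattern_label(fit.directions, dynamic=fit.dynamic)
        peaks = detect_peaks(fit) if fit.dynamic else []
        first = peaks[0] if peaks else None
        rows.append(
            {
                "gene": gene,
                "label": lab.label,
                "onset": lab.onset,
                "k": fit.K,
                "adjusted_r2": fit.adjusted_r2,
                "first_breakpoint": first_breakpoint(fit),
                "n_peaks": len(peaks),
                "peak_time": first.peak_time if first else np.nan,
                "peak_up_slope": first.up_slope if first else np.nan,
                "peak_down_slope": first.down_slope if first else np.nan,
            }
        )
    return pd.DataFrame(rows).set_index("gene")
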