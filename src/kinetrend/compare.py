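"""Cross-species and cross-condition kinetic statistics.

Three summary statistics quantify how kinetics differ between a fast
species A (mouse) and a slow species B (human):

* ΔM — Hodges–Lehmann shift (minutes) of B's event-time distribution
  (breakpoints or peak times) relative to A's, with a Wilcoxon
  rank-based confidence interval; positive when A is earlier. The paired
  variant uses Walsh averages of within-pair differences for 1:1
  ortholog pairs.
* ΔP% — difference in the percentage of genes in a category
  (immediate, monotonic, ...), with a continuity-corrected two-proportion
  z confidence interval.
* ΔS — ratio of median slope magnitudes A/B on unit-scaled expression
  (> 1 means faster A kinetics), with a within-group percentile-bootstrap
  confidence interval.

The exact Wilcoxon confidence intervals invert the Mann–Whitney and
signed-rank null distributions (Hollander–Wolfe construction); large or
tied samples fall back to the normal approximation on the ordered
pairwise differences.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import stats

from .grid import TimeGrid
from .preprocess import CountMatrix
from .trendfit import SAME, SegmentedFit

__all__ = [
    "OrthologMap",
    "ShiftEstimate",
    "ProportionDiff",
    "SlopeRatio",
    "OverlapReport",
    "load_ortholog_map",
    "delta_M",
    "delta_P",
    "delta_S",
    "subsample_every_k",
    "control_overlap",
    "intron_exon_change",
]

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# result containers

@dataclass(frozen=True)
class ShiftEstimate:
    delta_m: float
    ci_low: float
    ci_high: float
    conf: float
    paired: bool
    n_a: int
    n_b: int


@dataclass(frozen=True)
class ProportionDiff:
    delta_p_pct: float
    ci_low: float
    ci_high: float
    conf: float
    k_a: int
    n_a: int
    k_b: int
    n_b: int


@dataclass(frozen=True)
class SlopeRatio:
    delta_s: float
    ci_low: float
    ci_high: float
    conf: float
    n_a: int
    n_b: int
    n_boot: int
    seed: int


@dataclass(frozen=True)
class OrthologMap:
    """1:1 gene-id pairs (species A id, species B id)."""

    pairs: tuple
    n_dropped_ambiguous: int = 0

    def a_to_b(self) -> dict:
        return {a: b for a, b in self.pairs}


@dataclass(frozen=True)
class OverlapReport:
    n_dynamic_condition: int
    n_dynamic_control: int
    n_shared: int
    n_similar: int
    n_opposite: int
    breakpoints_condition: tuple
    breakpoints_control: tuple


# ---------------------------------------------------------------------------
# exact Wilcoxon null distributions (counts of the statistic's values)

@lru_cache(maxsize=None)
def _u_counts(m: int, n: int) -> tuple:
    """Frequencies of the Mann–Whitney U statistic, U = 0..m*n."""
    if m == 0 or n == 0:
        return (1.0,)
    a = np.zeros(m * n + 1)
    g1 = _u_counts(m - 1, n)
    a[n : n + len(g1)] += g1
    g2 = _u_counts(m, n - 1)
    a[: len(g2)] += g2
    return tuple(a.tolist())


def _qwilcox(p: float, m: int, n: int) -> int:
    """Smallest u with P(U <= u) >= p under the exact null."""
    c = np.asarray(_u_counts(m, n))
    cdf = np.cumsum(c) / c.sum()
    return int(np.searchsorted(cdf, p - 1e-12))


@lru_cache(maxsize=None)
def _signrank_counts(n: int) -> tuple:
    """Frequencies of the Wilcoxon signed-rank statistic, W = 0..n(n+1)/2."""
    M = n * (n + 1) // 2
    c = np.zeros(M + 1)
    c[0] = 1.0
    for k in range(1, n + 1):
        c[k:] = c[k:] + c[: M + 1 - k]
    return tuple(c.tolist())


def _qsignrank(p: float, n: int) -> int:
    c = np.asarray(_signrank_counts(n))
    cdf = np.cumsum(c) / c.sum()
    return int(np.searchsorted(cdf, p - 1e-12))


def _order_stat_ci(diffs: np.ndarray, q_exact, sd_approx: float, exact: bool, conf: float):
    """CI endpoints as order statistics of the sorted pairwise differences.

    ``q_exact`` supplies the exact lower critical index; the approximate
    path centers a normal band of width z * sd on the middle of the list.
    """
    M = diffs.size
    alpha = 1.0 - conf
    if exact:
        qu = q_exact(alpha / 2)
        if qu == 0:
            qu = 1
        lo, hi = diffs[qu - 1], diffs[M - qu]
    else:
        z = stats.norm.ppf(1 - alpha / 2)
        k = int(np.floor(M / 2 - z * sd_approx))
        k = min(max(k, 0), M // 2 - 1) if M >= 2 else 0
        lo, hi = diffs[k], diffs[M - 1 - k]
    return float(lo), float(hi)


def delta_M(times_a, times_b, paired: bool = False, conf: float = 0.99) -> ShiftEstimate:
    """Hodges–Lehmann shift of B's event times relative to A's.

    Unpaired: median of all pairwise differences b_j - a_i with the
    Mann–Whitney CI inversion. Paired: median of the Walsh averages of
    within-pair differences b_i - a_i with the signed-rank inversion.
    Exact inversion for small untied samples, continuity-matched normal
    approximation otherwise. Positive ΔM means A's events are earlier.
    """
    a = np.asarray(times_a, dtype=float)
    b = np.asarray(times_b, dtype=float)
    if a.size < 1 or b.size < 1:
        raise ValueError("both groups must be nonempty")
    if paired:
        if a.size != b.size:
            raise ValueError("paired shift needs equal-length, ortholog-ordered groups")
        d = b - a
        n = d.size
        iu = np.triu_indices(n)
        walsh = np.sort((d[:, None] + d[None, :])[iu] / 2.0)
        est = float(np.median(walsh))
        if np.all(walsh == walsh[0]):
            log.warning("all within-pair differences tied; CI degenerates to a point")
            return ShiftEstimate(est, est, est, conf, True, n, n)
        exact = n < 50 and np.unique(np.abs(d)).size == n and not np.any(d == 0)
        sd = np.sqrt(n * (n + 1) * (2 * n + 1) / 24.0)
        lo, hi = _order_stat_ci(walsh, lambda p: _qsignrank(p, n), sd, exact, conf)
        return ShiftEstimate(est, lo, hi, conf, True, n, n)
    m, n = a.size, b.size
    diffs = np.sort((b[None, :] - a[:, None]).ravel())
    est = float(np.median(diffs))
    if np.all(diffs == diffs[0]):
        log.warning("all pairwise differences tied; CI degenerates to a point")
        return ShiftEstimate(est, est, est, conf, False, m, n)
    pooled = np.concatenate([a, b])
    exact = m < 50 and n < 50 and np.unique(pooled).size == pooled.size
    sd = np.sqrt(m * n * (m + n + 1) / 12.0)
    lo, hi = _order_stat_ci(diffs, lambda p: _qwilcox(p, m, n), sd, exact, conf)
    return ShiftEstimate(est, lo, hi, conf, False, m, n)


def delta_P(k_a: int, n_a: int, k_b: int, n_b: int, conf: float = 0.99) -> ProportionDiff:
    """Percent-point difference p_A - p_B with the Yates-corrected
    two-proportion z confidence interval, scaled by 100."""
    for k, n in ((k_a, n_a), (k_b, n_b)):
        if n <= 0:
            raise ValueError("group sizes must be positive")
        if not 0 <= k <= n:
            raise ValueError("counts must satisfy 0 <= k <= n")
    p1, p2 = k_a / n_a, k_b / n_b
    d = p1 - p2
    z = stats.norm.ppf((1 + conf) / 2)
    width = z * np.sqrt(p1 * (1 - p1) / n_a + p2 * (1 - p2) / n_b) + 0.5 * (1 / n_a + 1 / n_b)
    lo = max(d - width, -1.0)
    hi = min(d + width, 1.0)
    return ProportionDiff(100 * d, 100 * lo, 100 * hi, conf, k_a, n_a, k_b, n_b)


def delta_S(
    slopes_a,
    slopes_b,
    conf: float = 0.99,
    n_boot: int = 10_000,
    seed: int = 0,
    magnitudes: bool = True,
) -> SlopeRatio:
    """Ratio of median slope magnitudes, median|A| / median|B|, with a
    within-group percentile-bootstrap CI. ``magnitudes=False`` keeps raw
    (signed) slopes — appropriate when both groups are all-positive up
    slopes. Deterministic given the seed."""
    a = np.asarray(slopes_a, dtype=float)
    b = np.asarray(slopes_b, dtype=float)
    if a.size < 1 or b.size < 1:
        raise ValueError("both slope groups must be nonempty")
    if magnitudes:
        a, b = np.abs(a), np.abs(b)
    med_b = np.median(b)
    if med_b == 0:
        raise ValueError("median of group B slopes is zero; ratio undefined")
    est = float(np.median(a) / med_b)
    rng = np.random.default_rng(seed)
    ia = rng.integers(0, a.size, size=(n_boot, a.size))
    ib = rng.integers(0, b.size, size=(n_boot, b.size))
    med_a_star = np.median(a[ia], axis=1)
    med_b_star = np.median(b[ib], axis=1)
    ok = med_b_star != 0
    ratios = med_a_star[ok] / med_b_star[ok]
    alpha = 1 - conf
    lo, hi = np.quantile(ratios, [alpha / 2, 1 - alpha / 2])
    return SlopeRatio(est, float(lo), float(hi), conf, a.size, b.size, n_boot, seed)


# ---------------------------------------------------------------------------
# supporting operations

def load_ortholog_map(path) -> OrthologMap:
    """Read a two-column TSV of (species-A id, species-B id) pairs and
    enforce a 1:1 mapping: exact duplicates collapse, ids involved in
    many-to-many relations are dropped entirely."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    if df.shape[1] < 2:
        raise ValueError("ortholog map must have two columns")
    df = df.iloc[:, :2].dropna().drop_duplicates()
    if df.empty:
        raise ValueError("no ortholog pairs in file")
    a_counts = df.iloc[:, 0].value_counts()
    b_counts = df.iloc[:, 1].value_counts()
    keep = df.iloc[:, 0].map(a_counts).eq(1) & df.iloc[:, 1].map(b_counts).eq(1)
    dropped = int((~keep).sum())
    if dropped:
        log.info("dropped %d ambiguous (many-to-many) ortholog rows", dropped)
    kept = df.loc[keep]
    if kept.empty:
        raise ValueError("no ortholog pairs left after enforcing 1:1 mapping")
    return OrthologMap(pairs=tuple(map(tuple, kept.itertuples(index=False))), n_dropped_ambiguous=dropped)


def subsample_every_k(m: CountMatrix, k: int = 3, offset: int = 0) -> CountMatrix:
    """Keep every k-th sample (indices offset, offset+k, ...), emulating a
    coarser sampling rate; the grid's nominal interval scales by k."""
    if k < 1:
        raise ValueError("k must be >= 1")
    idx = np.arange(offset, len(m.grid), k)
    if idx.size < 2:
        raise ValueError("fewer than two samples would remain")
    grid = TimeGrid(times=m.grid.times[idx], interval=m.grid.interval * k, dropped=m.grid.dropped)
    return CountMatrix(data=m.data.iloc[:, idx], grid=grid)


def _first_moving_direction(fit: SegmentedFit) -> str | None:
    for d in fit.directions:
        if d != SAME:
            return d
    return None


def control_overlap(
    fits_condition: dict[str, SegmentedFit],
    fits_control: dict[str, SegmentedFit],
) -> OverlapReport:
    """Overlap of dynamic gene sets between an experiment and its control,
    splitting shared genes into similar (same initial response direction)
    versus opposite, plus the two breakpoint-time distributions."""
    dyn_cond = {g for g, f in fits_condition.items() if f.dynamic}
    dyn_ctrl = {g for g, f in fits_control.items() if f.dynamic}
    if not (set(fits_condition) & set(fits_control)):
        raise ValueError("fit sets share no gene ids")
    shared = dyn_cond & dyn_ctrl
    similar = opposite = 0
    for g in shared:
        d1 = _first_moving_direction(fits_condition[g])
        d2 = _first_moving_direction(fits_control[g])
        if d1 is None or d2 is None:
            continue
        if d1 == d2:
            similar += 1
        else:
            opposite += 1
    bp_cond = tuple(float(b) for g in dyn_cond for b in fits_condition[g].breakpoints)
    bp_ctrl = tuple(float(b) for g in dyn_ctrl for b in fits_control[g].breakpoints)
    return OverlapReport(
        n_dynamic_condition=len(dyn_cond),
        n_dynamic_control=len(dyn_ctrl),
        n_shared=len(shared),
        n_similar=similar,
        n_opposite=opposite,
        breakpoints_condition=bp_cond,
        breakpoints_control=bp_ctrl,
    )


def intron_exon_change(
    exon: CountMatrix, intron: CountMatrix, window: int = 10
) -> tuple[pd.DataFrame, float]:
    """Treat the first and last ``window`` time points as conditions and
    compute, per gene, the change in mean (normalized) expression on exon
    and intron counts, plus the cross-gene Pearson correlation of the two
    changes."""
    if len(exon.grid) < 2 * window or len(intron.grid) < 2 * window:
        raise ValueError("grid shorter than twice the window")
    genes = exon.data.index.intersection(intron.data.index)
    if genes.empty:
        raise ValueError("no shared gene ids between exon and intron matrices")

    def _delta(cm: CountMatrix) -> pd.Series:
        d = cm.data.loc[genes]
        return d.iloc[:, -window:].mean(axis=1) - d.iloc[:, :window].mean(axis=1)

    out = pd.DataFrame({"delta_exon": _delta(exon), "delta_intron": _delta(intron)})
    corr = float(out["delta_exon"].corr(out["delta_intron"]))
    return out, corr
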