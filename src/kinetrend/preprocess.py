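"""Count-matrix preprocessing: exclusion lists, median-ratio normalization,
low-expression filtering and per-gene unit-interval scaling.

The stages mirror the standard RNA-seq trend-analysis recipe: remove genes
of unstable abundance (e.g. mitochondrial), divide out per-sample library
size factors estimated by the median-ratio (Anders–Huber) method, drop
genes whose average normalized expression is below 10, then scale each
remaining gene's profile to [0, 1] so fitted slopes are comparable across
genes and species.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grid import TimeGrid

__all__ = [
    "CountMatrix",
    "ScaledMatrix",
    "read_counts",
    "write_counts",
    "sum_lanes",
    "remove_genes",
    "median_ratio_normalize",
    "filter_low_expression",
    "scale_unit_interval",
]

log = logging.getLogger(__name__)

_TIME_RE = re.compile(r"^t?(\d+(?:\.\d+)?)(?:[._-].*)?$")


@dataclass
class CountMatrix:
    """Genes x timed samples of nonnegative (expected) counts.

    ``data`` is indexed by gene id with one column per sample, aligned with
    ``grid.times``. Raw and normalized matrices share this container.
    """

    data: pd.DataFrame
    grid: TimeGrid

    def __post_init__(self):
        if self.data.shape[1] != len(self.grid):
            raise ValueError(
                f"matrix has {self.data.shape[1]} columns but grid has {len(self.grid)} times"
            )
        if not self.data.index.is_unique:
            raise ValueError("gene ids must be unique")
        if self.data.size and (self.data.to_numpy() < 0).any():
            raise ValueError("counts must be nonnegative")

    @property
    def gene_ids(self) -> pd.Index:
        return self.data.index

    @property
    def n_genes(self) -> int:
        return self.data.shape[0]

    def row(self, gene) -> np.ndarray:
        return self.data.loc[gene].to_numpy(dtype=float)


@dataclass
class ScaledMatrix:
    """Per-gene profiles scaled to span exactly [0, 1] on each row."""

    X: pd.DataFrame
    grid: TimeGrid
    provenance: list[str] = field(default_factory=list)

    @property
    def gene_ids(self) -> pd.Index:
        return self.X.index


def _parse_time(col: str) -> float:
    m = _TIME_RE.match(str(col).strip())
    if not m:
        raise ValueError(f"cannot parse sampling time from column header {col!r}")
    return float(m.group(1))


def read_counts(
    path, interval: float | None = None, dropped=(), lane_map_path=None
) -> CountMatrix:
    """Read a genes x samples TSV/CSV whose headers encode time in minutes.

    Headers like ``t0004`` or ``120`` are parsed to minutes; columns are
    sorted by time. If ``interval`` is omitted it is inferred as the
    smallest positive spacing between sampled times. ``lane_map_path``
    optionally names a two-column TSV (column header, sample id) whose
    technical-replicate lanes are summed into one column per sample
    before parsing.
    """
    sep = "," if str(path).endswith(".csv") else "\t"
    df = pd.read_csv(path, sep=sep, index_col=0)
    if lane_map_path is not None:
        lm = pd.read_csv(lane_map_path, sep="\t", header=None, index_col=0).iloc[:, 0]
        df = sum_lanes(df, lane_map=lm)
    times = np.array([_parse_time(c) for c in df.columns])
    order = np.argsort(times, kind="stable")
    df = df.iloc[:, order]
    times = times[order]
    if interval is None:
        interval = float(np.min(np.diff(times))) if times.size > 1 else 1.0
    grid = TimeGrid(times=times, interval=interval, dropped=frozenset(dropped))
    df.columns = grid.sample_ids()
    return CountMatrix(data=df, grid=grid)


def write_counts(cm: CountMatrix, path) -> None:
    sep = "," if str(path).endswith(".csv") else "\t"
    out = cm.data.copy()
    out.columns = cm.grid.sample_ids()
    out.to_csv(path, sep=sep, index_label="gene")


def sum_lanes(df: pd.DataFrame, lane_map: pd.Series | None = None) -> pd.DataFrame:
    """Sum technical-replicate lanes into one column per time point.

    ``lane_map`` maps column name -> sample id; columns sharing a sample id
    are added together. Without a map, columns whose headers parse to the
    same time (e.g. ``t0010_L1``, ``t0010_L2``) are summed.
    """
    if lane_map is None:
        keys = [f"t{int(round(_parse_time(c))):04d}" for c in df.columns]
    else:
        keys = [lane_map[c] for c in df.columns]
    return df.T.groupby(keys, sort=True).sum().T


def remove_genes(m: CountMatrix, exclude) -> CountMatrix:
    """Drop rows whose gene id appears in ``exclude`` (absent ids ignored)."""
    exclude = set(exclude)
    present = m.data.index.intersection(exclude)
    missing = exclude - set(present)
    if missing:
        log.info("exclusion list: %d ids not present in matrix", len(missing))
    if len(present):
        log.info("removed %d excluded genes", len(present))
    return CountMatrix(data=m.data.drop(index=present), grid=m.grid)


def median_ratio_normalize(m: CountMatrix) -> tuple[CountMatrix, pd.Series]:
    """Median-ratio (Anders–Huber) normalization.

    Size factor for sample j is the median over reference genes of
    Y_ij / geomean_i, where reference genes are those with strictly
    positive counts in every sample (so the geometric mean is defined).
    Genes containing zeros are still returned normalized; they simply do
    not inform the size factors.
    """
    Y = m.data.to_numpy(dtype=float)
    ref = (Y > 0).all(axis=1)
    if not ref.any():
        raise ValueError(
            "median-ratio normalization needs at least one gene with "
            "strictly positive counts in every sample"
        )
    logY = np.log(Y[ref])
    log_geomean = logY.mean(axis=1)
    s = np.exp(np.median(logY - log_geomean[:, None], axis=0))
    factors = pd.Series(s, index=m.data.columns, name="size_factor")
    norm = pd.DataFrame(Y / s, index=m.data.index, columns=m.data.columns)
    return CountMatrix(data=norm, grid=m.grid), factors


def filter_low_expression(m: CountMatrix, threshold: float = 10.0) -> CountMatrix:
    """Drop genes with mean normalized expression strictly below ``threshold``.

    The inequality is strict: a gene averaging exactly the threshold is
    retained.
    """
    means = m.data.mean(axis=1)
    keep = means >= threshold
    n_drop = int((~keep).sum())
    if n_drop:
        log.info("low-expression filter removed %d genes (mean < %g)", n_drop, threshold)
    return CountMatrix(data=m.data.loc[keep], grid=m.grid)


def scale_unit_interval(m: CountMatrix) -> ScaledMatrix:
    """Scale each gene to [0, 1]: X = (Y - min Y) / (max Y - min Y).

    Genes with zero dynamic range (max == min) carry no trend information
    and are dropped.
    """
    Y = m.data.to_numpy(dtype=float)
    lo = Y.min(axis=1, keepdims=True)
    hi = Y.max(axis=1, keepdims=True)
    rng = hi - lo
    flat = (rng == 0).ravel()
    n_flat = int(flat.sum())
    provenance = []
    if n_flat:
        log.info("dropped %d genes with zero dynamic range", n_flat)
        provenance.append(f"dropped {n_flat} zero-dynamic-range genes")
    X = (Y[~flat] - lo[~flat]) / rng[~flat]
    if X.shape[0] == 0:
        raise ValueError("no genes left after unit-interval scaling")
    out = pd.DataFrame(X, index=m.data.index[~flat], columns=m.data.columns)
    provenance.append("scaled each gene to span [0, 1]")
    return ScaledMatrix(X=out, grid=m.grid, provenance=provenance)
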