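"""End-to-end orchestration: counts -> scaled profiles -> segmented fits ->
pattern labels -> cross-species comparison report.

Stages compose in the fixed order normalize -> filter -> scale -> fit ->
gate -> classify -> compare. Every stage's output is written as TSV with
enough columns to re-enter the pipeline (`fits_from_table`), so the CLI
subcommands can re-run stages independently.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import compare as cmp
from . import patterns as pat
from .grid import TimeGrid
from .preprocess import (
    CountMatrix,
    filter_low_expression,
    median_ratio_normalize,
    read_counts,
    remove_genes,
    scale_unit_interval,
    write_counts,
)
from .simulate import GroundTruth, SimConfig, simulate_counts, simulate_pair, write_ground_truth
from .trendfit import SAME, FitOptions, SegmentedFit, fit_matrix

__all__ = [
    "PipelineConfig",
    "DatasetResult",
    "ComparisonReport",
    "analyze_dataset",
    "compare_datasets",
    "run_pipeline",
    "fit_table",
    "fits_from_table",
]

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# fit tables

def fit_table(fits: dict[str, SegmentedFit]) -> pd.DataFrame:
    """Serialize fits to one row per gene (multi-valued fields ;-joined)."""
    rows = []
    for gene, f in fits.items():
        rows.append(
            {
                "gene": gene,
                "k": f.K,
                "adjusted_r2": f.adjusted_r2,
                "bic": f.bic,
                "rss": f.rss,
                "dynamic": f.dynamic,
                "breakpoints": ";".join(f"{b:.6g}" for b in f.breakpoints),
                "slopes": ";".join(f"{s:.8g}" for s in f.slopes),
                "directions": ";".join(f.directions),
                "segment_p": ";".join(f"{p:.6g}" for p in f.segment_p),
                "point_directions": ";".join(f.point_directions),
            }
        )
    return pd.DataFrame(rows).set_index("gene")


def _split_floats(s) -> np.ndarray:
    # single-valued fields come back from read_csv as plain floats
    if s is None:
        return np.empty(0)
    if isinstance(s, (int, float, np.floating)):
        return np.empty(0) if np.isnan(s) else np.array([float(s)])
    s = str(s).strip()
    if not s or s == "nan":
        return np.empty(0)
    return np.array([float(v) for v in s.split(";")])


def fits_from_table(df: pd.DataFrame) -> dict[str, SegmentedFit]:
    """Rebuild light-weight fits (enough for classification and comparison)
    from a serialized fit table."""
    fits = {}
    for gene, row in df.iterrows():
        dirs = str(row["directions"]).split(";")
        fits[gene] = SegmentedFit(
            K=int(row["k"]),
            breakpoints=_split_floats(row["breakpoints"]),
            intercept=np.nan,
            slopes=_split_floats(row["slopes"]),
            fitted=np.empty(0),
            rss=float(row.get("rss", np.nan)),
            bic=float(row.get("bic", np.nan)),
            adjusted_r2=float(row["adjusted_r2"]),
            segment_p=_split_floats(row.get("segment_p", "")),
            directions=dirs,
            point_directions=str(row.get("point_directions", "")).split(";"),
            dynamic=bool(row["dynamic"]),
            gene=gene,
        )
    return fits


# ---------------------------------------------------------------------------
# per-dataset analysis

@dataclass
class DatasetResult:
    name: str
    normalized: CountMatrix
    size_factors: pd.Series
    fits: dict[str, SegmentedFit]
    fit_table: pd.DataFrame
    pattern_table: pd.DataFrame
    n_input_genes: int

    def dynamic_fits(self) -> dict[str, SegmentedFit]:
        return {g: f for g, f in self.fits.items() if f.dynamic}


def analyze_dataset(
    counts: CountMatrix,
    opts: FitOptions,
    name: str = "dataset",
    exclude=(),
    mean_threshold: float = 10.0,
) -> DatasetResult:
    """Run one dataset through exclusion, normalization, filtering, scaling,
    segmented fitting and pattern classification."""
    if counts.n_genes == 0:
        raise ValueError(f"{name}: preprocessing received an empty count matrix")
    t0 = time.perf_counter()
    n_in = counts.n_genes
    cm = remove_genes(counts, exclude) if exclude else counts
    cm, factors = median_ratio_normalize(cm)
    cm = filter_low_expression(cm, mean_threshold)
    scaled = scale_unit_interval(cm)
    fits = fit_matrix(scaled, opts)
    res = DatasetResult(
        name=name,
        normalized=cm,
        size_factors=factors,
        fits=fits,
        fit_table=fit_table(fits),
        pattern_table=pat.pattern_table(fits),
        n_input_genes=n_in,
    )
    log.info(
        "%s: %d genes in, %d fit (%d dynamic) in %.1fs",
        name, n_in, len(fits), sum(f.dynamic for f in fits.values()), time.perf_counter() - t0,
    )
    return res


# ---------------------------------------------------------------------------
# cross-species comparison

@dataclass
class ComparisonReport:
    """ΔM / ΔP% / ΔS estimates with the gene sets and censuses behind them.

    ΔM entries are positive when species A's events are earlier; ΔP
    entries are reported as percent in B minus percent in A, matching the
    human-versus-mouse orientation of the reference analysis; ΔS entries
    are A-over-B ratios of median slope magnitudes.
    """

    entries: dict = field(default_factory=dict)
    census_a: pd.DataFrame | None = None
    census_b: pd.DataFrame | None = None
    counts: dict = field(default_factory=dict)

    def summary(self) -> pd.DataFrame:
        rows = []
        for name, e in self.entries.items():
            if isinstance(e, cmp.ShiftEstimate):
                rows.append({"statistic": name, "kind": "delta_M", "estimate": e.delta_m,
                             "ci_low": e.ci_low, "ci_high": e.ci_high, "n_a": e.n_a, "n_b": e.n_b})
            elif isinstance(e, cmp.ProportionDiff):
                rows.append({"statistic": name, "kind": "delta_P_pct", "estimate": e.delta_p_pct,
                             "ci_low": e.ci_low, "ci_high": e.ci_high, "n_a": e.n_a, "n_b": e.n_b})
            elif isinstance(e, cmp.SlopeRatio):
                rows.append({"statistic": name, "kind": "delta_S", "estimate": e.delta_s,
                             "ci_low": e.ci_low, "ci_high": e.ci_high, "n_a": e.n_a, "n_b": e.n_b})
        return pd.DataFrame(rows).set_index("statistic")


def _first_peaks(fits: dict[str, SegmentedFit]) -> dict[str, pat.PeakCall]:
    out = {}
    for g, f in fits.items():
        if not f.dynamic:
            continue
        peaks = pat.detect_peaks(f)
        if peaks:
            out[g] = peaks[0]  # only the first peak feeds the statistics
    return out


def _immediate_slopes(fits: dict[str, SegmentedFit], direction: str) -> list[float]:
    out = []
    for f in fits.values():
        if f.dynamic and f.directions and f.directions[0] == direction:
            out.append(float(f.slopes[0]))
    return out


def compare_datasets(
    res_a: DatasetResult,
    res_b: DatasetResult,
    orthologs: cmp.OrthologMap | None = None,
    conf: float = 0.99,
    n_boot: int = 10_000,
    seed: int = 0,
    census_cutpoints=(60, 100, 250),
) -> ComparisonReport:
    """All cross-species statistics between species A (fast) and B (slow).

    With no ortholog map, genes sharing an id across the two datasets are
    treated as 1:1 orthologs (the synthetic-pair convention).
    """
    fits_a = res_a.dynamic_fits()
    fits_b = res_b.dynamic_fits()
    if orthologs is None:
        shared = sorted(set(res_a.fits) & set(res_b.fits))
        pairs = tuple((g, g) for g in shared)
    else:
        pairs = orthologs.pairs

    rep = ComparisonReport()
    ent = rep.entries

    # --- event-time shifts -------------------------------------------------
    bp_first_a = [pat.first_breakpoint(f) for f in fits_a.values() if f.K >= 1]
    bp_first_b = [pat.first_breakpoint(f) for f in fits_b.values() if f.K >= 1]
    if bp_first_a and bp_first_b:
        ent["first_breakpoint_shift"] = cmp.delta_M(bp_first_a, bp_first_b, conf=conf)
    bp_all_a = [float(b) for f in fits_a.values() for b in f.breakpoints]
    bp_all_b = [float(b) for f in fits_b.values() for b in f.breakpoints]
    if bp_all_a and bp_all_b:
        ent["all_breakpoint_shift"] = cmp.delta_M(bp_all_a, bp_all_b, conf=conf)

    paired_a, paired_b = [], []
    for ga, gb in pairs:
        fa, fb = fits_a.get(ga), fits_b.get(gb)
        if fa is not None and fb is not None and fa.K >= 1 and fb.K >= 1:
            paired_a.append(float(fa.breakpoints[0]))
            paired_b.append(float(fb.breakpoints[0]))
    if len(paired_a) >= 2:
        ent["ortholog_first_breakpoint_shift"] = cmp.delta_M(paired_a, paired_b, paired=True, conf=conf)

    peaks_a = _first_peaks(fits_a)
    peaks_b = _first_peaks(fits_b)
    if peaks_a and peaks_b:
        ent["peak_time_shift"] = cmp.delta_M(
            [p.peak_time for p in peaks_a.values()],
            [p.peak_time for p in peaks_b.values()],
            conf=conf,
        )
    both_peak = [(ga, gb) for ga, gb in pairs if ga in peaks_a and gb in peaks_b]
    if len(both_peak) >= 2:
        ent["ortholog_peak_time_shift"] = cmp.delta_M(
            [peaks_a[ga].peak_time for ga, _ in both_peak],
            [peaks_b[gb].peak_time for _, gb in both_peak],
            paired=True,
            conf=conf,
        )

    # --- category proportions (percent in B minus percent in A) -----------
    def _prop(predicate):
        ka = sum(predicate(f) for f in fits_a.values())
        kb = sum(predicate(f) for f in fits_b.values())
        return cmp.delta_P(kb, max(len(fits_b), 1), ka, max(len(fits_a), 1), conf=conf)

    if fits_a and fits_b:
        ent["immediate_pct_diff"] = _prop(lambda f: f.directions[0] != SAME)
        ent["monotonic_pct_diff"] = _prop(lambda f: f.K == 0)

    # --- slope-magnitude ratios (A over B) ---------------------------------
    if both_peak:
        up_a = [peaks_a[ga].up_slope for ga, _ in both_peak]
        up_b = [peaks_b[gb].up_slope for _, gb in both_peak]
        down_a = [peaks_a[ga].down_slope for ga, _ in both_peak]
        down_b = [peaks_b[gb].down_slope for _, gb in both_peak]
        ent["ortholog_peak_up_slope_ratio"] = cmp.delta_S(up_a, up_b, conf, n_boot, seed)
        ent["ortholog_peak_down_slope_ratio"] = cmp.delta_S(down_a, down_b, conf, n_boot, seed + 1)
    if peaks_a and peaks_b:
        ent["peak_up_slope_ratio"] = cmp.delta_S(
            [p.up_slope for p in peaks_a.values()],
            [p.up_slope for p in peaks_b.values()],
            conf, n_boot, seed + 2,
        )
        ent["peak_down_slope_ratio"] = cmp.delta_S(
            [p.down_slope for p in peaks_a.values()],
            [p.down_slope for p in peaks_b.values()],
            conf, n_boot, seed + 3,
        )
    up_im_a = _immediate_slopes(fits_a, "up")
    up_im_b = _immediate_slopes(fits_b, "up")
    if up_im_a and up_im_b:
        ent["immediate_up_slope_ratio"] = cmp.delta_S(up_im_a, up_im_b, conf, n_boot, seed + 4)
    dn_im_a = _immediate_slopes(fits_a, "down")
    dn_im_b = _immediate_slopes(fits_b, "down")
    if dn_im_a and dn_im_b:
        ent["immediate_down_slope_ratio"] = cmp.delta_S(dn_im_a, dn_im_b, conf, n_boot, seed + 5)

    rep.census_a = pat.breakpoint_census(fits_a.values(), census_cutpoints)
    rep.census_b = pat.breakpoint_census(fits_b.values(), census_cutpoints)
    rep.counts = {
        "n_dynamic_a": len(fits_a),
        "n_dynamic_b": len(fits_b),
        "n_monotonic_a": sum(f.K == 0 for f in fits_a.values()),
        "n_monotonic_b": sum(f.K == 0 for f in fits_b.values()),
        "n_peak_a": len(peaks_a),
        "n_peak_b": len(peaks_b),
        "n_ortholog_pairs": len(pairs),
    }
    return rep


# ---------------------------------------------------------------------------
# full pipeline

@dataclass
class PipelineConfig:
    """Declarative run description; serializable to YAML.

    Either ``simulate=True`` (a paired synthetic experiment drawn from
    ``sim``) or paths to two count matrices. Fit options follow the grid
    spacing: 5-point minimum segments on 4-minute grids, 3-point on
    10-minute grids.
    """

    out_dir: str = "results/pipeline"
    simulate: bool = True
    sim: SimConfig = field(default_factory=SimConfig)
    counts_a: str | None = None
    counts_b: str | None = None
    exclude_path: str | None = None
    ortholog_path: str | None = None
    fit_a: FitOptions = field(default_factory=lambda: FitOptions(min_seg_points=5))
    fit_b: FitOptions = field(default_factory=lambda: FitOptions(min_seg_points=3))
    conf: float = 0.99
    n_boot: int = 10_000
    seed: int = 0

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        g = self.sim.grid
        gb = self.sim.grid_b
        d["sim"]["grid"] = {"interval": g.interval, "end": float(g.times[-1]), "dropped": sorted(g.dropped)}
        d["sim"]["grid_b"] = {"interval": gb.interval, "end": float(gb.times[-1]), "dropped": sorted(gb.dropped)}
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        from .grid import make_time_grid

        d = yaml.safe_load(Path(path).read_text())
        sim = d.pop("sim", {})
        for key in ("grid", "grid_b"):
            if key in sim and isinstance(sim[key], dict):
                sim[key] = make_time_grid(sim[key]["interval"], sim[key]["end"], sim[key].get("dropped", ()))
        cfg = cls(
            **{k: v for k, v in d.items() if k not in ("fit_a", "fit_b")},
            fit_a=FitOptions(**d.get("fit_a", {})) if "fit_a" in d else FitOptions(min_seg_points=5),
            fit_b=FitOptions(**d.get("fit_b", {})) if "fit_b" in d else FitOptions(min_seg_points=3),
        )
        if sim:
            cfg.sim = SimConfig(**sim)
        return cfg


@dataclass
class PipelineResult:
    res_a: DatasetResult
    res_b: DatasetResult
    report: ComparisonReport
    truth_a: GroundTruth | None = None
    truth_b: GroundTruth | None = None
    out_dir: Path | None = None


def _load_exclusions(path) -> list[str]:
    if path is None:
        return []
    return [ln.strip() for ln in Path(path).read_text().splitlines() if ln.strip()]


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run the full analysis and write every artifact under ``out_dir``.

    Deterministic given the config (all randomness flows from
    ``config.seed`` / the simulation seeds).
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    exclude = _load_exclusions(config.exclude_path)
    truth_a = truth_b = None

    if config.simulate:
        pair = simulate_pair(config.sim)
        truth_a, truth_b = pair.truth_a, pair.truth_b
        counts_a, sf_a = simulate_counts(pair.profiles_a, config.sim, grid=config.sim.grid,
                                         seed=config.sim.seed)
        counts_b, sf_b = simulate_counts(pair.profiles_b, config.sim, grid=config.sim.grid_b,
                                         seed=config.sim.seed + 1)
        write_counts(counts_a, out / "counts_a.tsv")
        write_counts(counts_b, out / "counts_b.tsv")
        write_ground_truth(truth_a, out / "truth_a.tsv")
        write_ground_truth(truth_b, out / "truth_b.tsv")
        orthologs = None
    else:
        if not (config.counts_a and config.counts_b):
            raise ValueError("non-simulated runs need counts_a and counts_b paths")
        counts_a = read_counts(config.counts_a)
        counts_b = read_counts(config.counts_b)
        orthologs = cmp.load_ortholog_map(config.ortholog_path) if config.ortholog_path else None

    res_a = analyze_dataset(counts_a, config.fit_a, name="species_a", exclude=exclude)
    res_b = analyze_dataset(counts_b, config.fit_b, name="species_b", exclude=exclude)
    report = compare_datasets(
        res_a, res_b, orthologs, conf=config.conf, n_boot=config.n_boot, seed=config.seed
    )

    for res in (res_a, res_b):
        res.fit_table.to_csv(out / f"fits_{res.name}.tsv", sep="\t")
        res.pattern_table.to_csv(out / f"patterns_{res.name}.tsv", sep="\t")
        res.size_factors.to_csv(out / f"size_factors_{res.name}.tsv", sep="\t", header=True)
    report.summary().to_csv(out / "comparison_summary.tsv", sep="\t")
    report.census_a.to_csv(out / "census_species_a.tsv", sep="\t", index=False)
    report.census_b.to_csv(out / "census_species_b.tsv", sep="\t", index=False)
    (out / "comparison_counts.json").write_text(json.dumps(report.counts, indent=2))
    config.to_yaml(out / "config.yaml")
    return PipelineResult(res_a, res_b, report, truth_a, truth_b, out)
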