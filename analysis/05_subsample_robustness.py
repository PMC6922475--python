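#!/usr/bin/env python
"""Sampling-rate robustness: thin the fast series to every third sample
(nominal 12-minute spacing) and re-run the whole comparison.

If the cross-species contrasts were artifacts of the fast species' denser
sampling, they should vanish here; instead the earlier breakpoints, the
monotonic-gene deficit and the steeper up-slopes should persist. Writes
the thinned fit table and comparison under results/.
"""

import json
from pathlib import Path

import pandas as pd

from kinetrend.compare import subsample_every_k
from kinetrend.pipeline import DatasetResult, analyze_dataset, compare_datasets, fit_table, fits_from_table
from kinetrend.preprocess import read_counts
from kinetrend.trendfit import FitOptions

ROOT = Path(__file__).resolve().parent.parent / "results"
SEED = 20191210


def main():
    cm = read_counts(ROOT / "data" / "counts_fast.tsv")
    thin = subsample_every_k(cm, k=3)
    print(f"thinned fast series from {len(cm.grid)} to {len(thin.grid)} samples "
          f"({thin.grid.interval:.0f}-minute nominal spacing)")
    res_a = analyze_dataset(thin, FitOptions(min_seg_points=5), name="fast_every3rd")
    res_a.fit_table.to_csv(ROOT / "fits_fast_every3rd.tsv", sep="\t")

    fits_b = fits_from_table(pd.read_csv(ROOT / "fits_slow.tsv", sep="\t", index_col=0))
    res_b = DatasetResult("slow", None, None, fits_b, fit_table(fits_b), None, len(fits_b))
    rep = compare_datasets(res_a, res_b, seed=SEED, n_boot=10_000)
    rep.summary().to_csv(ROOT / "comparison_summary_every3rd.tsv", sep="\t")
    (ROOT / "comparison_counts_every3rd.json").write_text(json.dumps(rep.counts, indent=2))

    shift = rep.entries["ortholog_first_breakpoint_shift"]
    up = rep.entries.get("peak_up_slope_ratio")
    print(
        f"at 12-minute sampling the fast species still breaks first: "
        f"ΔM = {shift.delta_m:.0f} min (99% CI {shift.ci_low:.0f}–{shift.ci_high:.0f})"
    )
    if up:
        print(f"and still climbs faster: ΔS_up = {up.delta_s:.2f} "
              f"(99% CI {up.ci_low:.2f}–{up.ci_high:.2f})")
    print("monotonic dynamic genes: fast", rep.counts["n_monotonic_a"],
          "vs slow", rep.counts["n_monotonic_b"])


if __name__ == "__main__":
    main()
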