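#!/usr/bin/env python
"""Classify every fitted gene into the pattern taxonomy and census the
breakpoints.

Direction sequences map to monotonic up/down, (delayed) peak, (delayed)
dip, delayed up/down, immediate on/off or cyclic; genes failing the
adjusted-R^2 gate are not dynamic. Breakpoints are counted before 60, 100
and 250 minutes per species. Writes pattern tables and censuses under
results/ and prints the label breakdown.
"""

from pathlib import Path

import pandas as pd

from kinetrend.patterns import breakpoint_census, pattern_table
from kinetrend.pipeline import fits_from_table

ROOT = Path(__file__).resolve().parent.parent / "results"


def main():
    for name in ("fast", "slow"):
        fits = fits_from_table(pd.read_csv(ROOT / f"fits_{name}.tsv", sep="\t", index_col=0))
        pat = pattern_table(fits)
        pat.to_csv(ROOT / f"patterns_{name}.tsv", sep="\t")
        census = breakpoint_census(
            (f for f in fits.values() if f.dynamic), cutpoints=(60, 100, 250)
        )
        census.to_csv(ROOT / f"census_{name}.tsv", sep="\t", index=False)
        counts = pat.loc[pat["label"] != "not_dynamic", "label"].value_counts()
        print(f"\n{name} species — dynamic pattern counts:")
        print(counts.to_string())
        print("breakpoints before 60/100/250 min:", census["n_breakpoints"].tolist())


if __name__ == "__main__":
    main()
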