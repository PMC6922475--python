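# kinetrend

Segmented-trend kinetics for minute-scale RNA-seq time courses:
breakpoint regression with BIC model selection, an expression-pattern
taxonomy, and nonparametric cross-species kinetic statistics — plus a
negative-binomial time-course simulator with recorded ground truth so the
whole pipeline is testable end to end.

## The problem

When pluripotent stem cells of different species receive the same
differentiation signal, their transcriptomes respond at species-specific
speeds: mouse expression programs are compressed, human ones protracted.
Quantifying that requires sampling RNA-seq every few minutes and then
answering, per gene: *when* does expression change trend (breakpoints),
*what shape* is the response (peak, dip, monotonic, delayed, cyclic), and
*how fast* does it move (segment slopes) — and then comparing those
quantities across species over orthologous genes. This package implements
that analysis for anyone with gene × timed-sample count matrices (bulk
RNA-seq expected counts, headers encoding minutes).

## The model

Counts are median-ratio normalized (Anders–Huber size factors), genes
with mean normalized expression below 10 are dropped, and each remaining
gene is scaled to the unit interval,
X<sub>i,j</sub> = (Y<sub>i,j</sub> − min<sub>j</sub> Y<sub>i,j</sub>) /
(max<sub>j</sub> Y<sub>i,j</sub> − min<sub>j</sub> Y<sub>i,j</sub>),
so slopes are comparable across genes and species. Expression is then a
continuous piecewise-linear function of time,

    x(t) = β₀ + β₁·t + Σₖ γₖ·(t − bₖ)₊ ,

with K = 0…5 breakpoints chosen by BIC (parameter count p = 2 + 2K),
every segment required to hold at least 5 observed points on 4-minute
grids or 3 on 10-minute grids, and segments labeled up / down / same by a
slope t-test at p < 0.2. Genes with adjusted R² > 0.2 are "dynamic".
Direction sequences map to the pattern taxonomy (peak = up-down or
up-same-down, delayed variants with a leading flat segment, cyclic for
repeated excursions, …).

Cross-species contrasts, all with 99% confidence intervals:

* **ΔM** — Hodges–Lehmann shift (minutes) of the slow species' event
  times relative to the fast species' (Wilcoxon CI inversion; paired
  variant for 1:1 orthologs); positive when the fast species is earlier.
* **ΔP%** — difference in the percentage of genes in a category
  (continuity-corrected two-proportion z interval).
* **ΔS** — ratio of median slope magnitudes, fast over slow, on
  unit-scaled expression (percentile bootstrap); ΔS > 1 means faster
  fast-species kinetics.

See `docs/methods.md` for the full model account, numerical choices and
limitations.

## Worked example

The `analysis/` scripts run the complete study on simulated data: a fast
species sampled every 4 minutes (145 samples, six dropped times) paired
with a slow species sampled every 10 minutes (61 samples), 400 shared
genes, slow-species kinetics dilated 2.5× in time.

```sh
python analysis/01_simulate_pair.py
python analysis/02_fit_trends.py
python analysis/03_classify_patterns.py
python analysis/04_compare_species.py
python analysis/05_subsample_robustness.py
python analysis/06_calibrate_r2.py
```

The fitting step reports

```
fast: 400 genes in, 400 fit, 163 dynamic (adjusted R^2 > 0.2) carrying 180 breakpoints
slow: 400 genes in, 400 fit, 166 dynamic (adjusted R^2 > 0.2) carrying 168 breakpoints
```

and the comparison step prints, among the full ΔM/ΔP%/ΔS summary table,

```
first breakpoints occur ΔM = 104 min earlier in the fast species (99% CI 80–126; n = 105 ortholog pairs)
peak up-slopes are ΔS = 1.86x steeper in the fast species (99% CI 1.30–2.54)
monotonic dynamic genes: fast 27 vs slow 51
```

Read: over orthologs dynamic in both species, the fast species changes
trend about 104 minutes earlier (the CI excludes zero), climbs to its
peaks about 1.9× faster per minute of scaled expression, and has fewer
monotonic (breakpoint-free) genes because the slow species' protracted
trends run past the 10-hour window uninterrupted. Script 05 repeats the
comparison with the fast series thinned to every third sample (12-minute
spacing) and the same qualitative contrasts persist, so they are not an
artifact of denser sampling. All tables land under `results/`.

The same stages are available as a CLI for file-based use on real count
matrices (`kinetrend simulate | fit | classify | compare | report |
calibrate-r2`; see `kinetrend --help`), with an optional exclusion list
for mitochondrial genes and a two-column TSV ortholog map for paired
statistics.

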