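"""Synthetic minute-scale expression time courses with known kinetics.

Each gene is a continuous piecewise-linear mean trend on the unit
interval, drawn from the pattern taxonomy (monotonic, peak, dip, delayed
variants, on/off plateaus, cyclic, flat), mapped to an expected-count
scale and observed through negative-binomial noise with per-sample
library-size factors. The generator records full ground truth (true
breakpoints, slopes, labels, peak times) so breakpoint recovery, direction
calls, pattern labels and cross-species statistics can all be scored.

Paired simulations emulate a fast species A (mouse-like 4-minute grid)
against a slow species B (human-like 10-minute grid): gene shapes are
drawn on the fast timeline and dilated by ``kinetic_speedup`` for B, so
A's breakpoints sit at b/speedup of B's and A's interior slopes are
speedup-fold steeper. Events dilated past the observation window are
truncated for B — those genes appear monotonic in the slow species, the
same censoring that makes protracted kinetics look monotonic in a fixed
10-hour window.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grid import TimeGrid, human_grid, mouse_grid
from .patterns import pattern_label
from .preprocess import CountMatrix

__all__ = [
    "PatternSpec",
    "SimConfig",
    "GroundTruth",
    "SimPair",
    "default_pattern_mix",
    "simulate_profiles",
    "simulate_counts",
    "simulate_pair",
    "write_ground_truth",
]

UP, DOWN, SAME = "up", "down", "same"

# direction templates per latent pattern class
_TEMPLATES = {
    "flat": (SAME,),
    "monotonic_up": (UP,),
    "monotonic_down": (DOWN,),
    "peak": (UP, DOWN),
    "dip": (DOWN, UP),
    "delayed_peak": (SAME, UP, DOWN),
    "delayed_dip": (SAME, DOWN, UP),
    "delayed_up": (SAME, UP),
    "delayed_down": (SAME, DOWN),
    "immediate_on": (UP, SAME),
    "immediate_off": (DOWN, SAME),
    "cyclic": (UP, DOWN, UP),
}

# segment geometry on the fast timeline (minutes): most stimulus-response
# transitions complete within roughly forty minutes to two hours, with a
# slow tail of protracted first responses (~20% of moving genes, matching
# the observed share of fast-species first breakpoints beyond 250 min);
# flat onsets are long enough to be distinguishable under the
# minimum-segment rule. Protracted first segments are the censoring
# channel: dilated by the species speedup they leave the observation
# window, so the slow species reads them as monotonic.
_SEG_DUR_LO, _SEG_DUR_HI = 40.0, 120.0   # fast up/down segment durations
_SLOW_DUR_LO, _SLOW_DUR_HI = 150.0, 450.0  # protracted first segments
_SLOW_PROB = 0.2                         # share of protracted first responses
_DELAY_LO, _DELAY_HI = 60.0, 140.0       # flat-onset duration, delayed classes
_BP_CAP = 540.0                          # breakpoints stay identifiable inside the window
_V_LO, _V_HI = 0.02, 0.98                # node-value band
_MIN_AMP = 0.65                          # minimum per-segment excursion


def default_pattern_mix() -> dict[str, float]:
    """Latent class probabilities for a stimulus-response transcriptome.

    A majority of genes are stable (flat): that is what real transcriptomes
    look like, and it is the standing assumption of median-ratio
    normalization — with most genes unchanging, the per-sample median
    count ratio tracks library size rather than the shared response trend.
    Among dynamic genes the shares echo the observed censuses: ~90%
    immediate, ~20% monotonic, peaks the most common non-monotonic shape.
    """
    return {
        "flat": 0.55,
        "peak": 0.14,
        "dip": 0.07,
        "monotonic_up": 0.05,
        "monotonic_down": 0.05,
        "immediate_on": 0.03,
        "immediate_off": 0.03,
        "delayed_peak": 0.015,
        "delayed_dip": 0.01,
        "delayed_up": 0.01,
        "delayed_down": 0.01,
        "cyclic": 0.035,
    }


@dataclass(frozen=True)
class PatternSpec:
    """True piecewise-linear kinetics of one gene.

    ``breakpoints`` are the times (minutes) where the slope changes;
    ``slopes`` are per-segment, in scaled-expression units per minute.
    """

    pattern_class: str
    breakpoints: tuple
    slopes: tuple
    baseline: float
    onset: str  # immediate | delayed | none

    def __post_init__(self):
        if len(self.slopes) != len(self.breakpoints) + 1:
            raise ValueError("need exactly one more slope than breakpoints")
        if len(self.breakpoints) > 1 and np.any(np.diff(self.breakpoints) <= 0):
            raise ValueError("breakpoints must be strictly increasing")

    def node_values(self, end: float) -> tuple[np.ndarray, np.ndarray]:
        """(node times, node values): curve vertices at 0, b_1..b_K, end."""
        tt = np.concatenate([[0.0], np.asarray(self.breakpoints, dtype=float), [end]])
        vv = np.concatenate([[self.baseline], self.baseline + np.cumsum(np.asarray(self.slopes) * np.diff(tt))])
        return tt, vv

    def curve(self, times: np.ndarray, end: float | None = None) -> np.ndarray:
        """Evaluate the mean trend at the given times."""
        end = float(times[-1]) if end is None else end
        tt, vv = self.node_values(end)
        return np.interp(times, tt, vv)

    @property
    def directions(self) -> tuple:
        out = []
        for s in self.slopes:
            out.append(SAME if s == 0 else (UP if s > 0 else DOWN))
        return tuple(out)


@dataclass(frozen=True)
class SimConfig:
    """Study conditions of a synthetic experiment.

    NB noise has variance mu + dispersion * mu^2 (dispersion 0 is the
    Poisson limit). ``mean_count_scale`` maps the unit-scaled trend x to
    expected counts mu = scale * (0.1 + 0.9 x), keeping mu positive so
    geometric means exist. ``seed`` drives only the count noise and size
    factors; the gene shapes themselves come from ``profile_seed``, so
    re-drawing noise never changes the ground truth.
    """

    n_genes: int = 500
    grid: TimeGrid = field(default_factory=mouse_grid)
    grid_b: TimeGrid = field(default_factory=human_grid)
    dispersion: float = 0.05
    mean_count_scale: float = 500.0
    size_factor_sigma: float = 0.15
    pattern_mix: dict = field(default_factory=default_pattern_mix)
    kinetic_speedup: float = 2.5
    seed: int = 0
    profile_seed: int = 20191209

    def __post_init__(self):
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        if self.kinetic_speedup <= 0:
            raise ValueError("kinetic_speedup must be > 0")
        probs = np.array(list(self.pattern_mix.values()), dtype=float)
        if np.any(probs < 0) or abs(probs.sum() - 1.0) > 1e-8:
            raise ValueError("pattern_mix must be nonnegative and sum to 1")
        unknown = set(self.pattern_mix) - set(_TEMPLATES)
        if unknown:
            raise ValueError(f"unknown pattern classes: {sorted(unknown)}")


@dataclass
class GroundTruth:
    """True parameters per gene: spec plus derived labels and peak calls."""

    table: pd.DataFrame  # indexed by gene
    specs: dict[str, PatternSpec]


@dataclass
class SimPair:
    """A paired two-species simulation sharing gene identities."""

    profiles_a: pd.DataFrame
    truth_a: GroundTruth
    profiles_b: pd.DataFrame
    truth_b: GroundTruth
    config: SimConfig


# ---------------------------------------------------------------------------
# spec sampling

def _sample_breakpoints(rng, dirs) -> np.ndarray:
    """Breakpoints from per-segment durations: flat onsets 60-140 min,
    moving segments 40-120 min with a 20% protracted (150-450 min) tail on
    the first moving segment, the final segment running to the window end.
    K <= 2 under these templates; resampling keeps breakpoints interior."""
    for _ in range(100):
        durations = []
        first_moving = True
        for d in dirs[:-1]:  # last segment takes the remainder
            if d == SAME:
                durations.append(rng.uniform(_DELAY_LO, _DELAY_HI))
            elif first_moving and rng.uniform() < _SLOW_PROB:
                durations.append(rng.uniform(_SLOW_DUR_LO, _SLOW_DUR_HI))
                first_moving = False
            else:
                durations.append(rng.uniform(_SEG_DUR_LO, _SEG_DUR_HI))
                first_moving = False
        b = np.cumsum(durations)
        if b.size == 0 or b[-1] <= _BP_CAP:
            return b
    return np.cumsum([(_BP_CAP / max(len(durations), 1))] * len(durations))


def _sample_node_values(rng, dirs) -> np.ndarray:
    moving = [d for d in dirs if d != SAME]
    if not moving:
        v0 = rng.uniform(0.3, 0.7)
        return np.full(len(dirs) + 1, v0)
    v0 = rng.uniform(_V_LO, 0.25) if moving[0] == UP else rng.uniform(0.75, _V_HI)
    vv = [v0]
    for d in dirs:
        v = vv[-1]
        if d == SAME:
            vv.append(v)
        elif d == UP:
            hi = _V_HI - v
            vv.append(v + rng.uniform(min(_MIN_AMP, hi - 1e-6), max(hi, _MIN_AMP + 1e-6)))
        else:
            lo = v - _V_LO
            vv.append(v - rng.uniform(min(_MIN_AMP, lo - 1e-6), max(lo, _MIN_AMP + 1e-6)))
    return np.clip(np.asarray(vv), 0.0, 1.0)


def _make_spec(rng, pattern_class: str, end: float) -> PatternSpec:
    dirs = list(_TEMPLATES[pattern_class])
    if pattern_class == "cyclic" and rng.uniform() < 0.5:
        dirs = [DOWN, UP, DOWN]
    b = _sample_breakpoints(rng, dirs)
    vv = _sample_node_values(rng, dirs)
    tt = np.concatenate([[0.0], b, [end]])
    slopes = np.diff(vv) / np.diff(tt)
    slopes[np.array(dirs) == SAME] = 0.0
    onset = "none" if pattern_class == "flat" else ("delayed" if dirs[0] == SAME else "immediate")
    return PatternSpec(
        pattern_class=pattern_class,
        breakpoints=tuple(b.tolist()),
        slopes=tuple(slopes.tolist()),
        baseline=float(vv[0]),
        onset=onset,
    )


def _truth_peaks(spec: PatternSpec):
    """First true peak (time, up slope, down slope) or None."""
    dirs = spec.directions
    for i, d in enumerate(dirs):
        if d != UP:
            continue
        j = i + 1
        if j < len(dirs) and dirs[j] == SAME:
            j += 1
        if j < len(dirs) and dirs[j] == DOWN:
            return float(spec.breakpoints[i]), spec.slopes[i], spec.slopes[j]
    return None


def _truth_row(gene, spec: PatternSpec, grid: TimeGrid):
    curve = spec.curve(grid.times, end=float(grid.times[-1]))
    crange = float(curve.max() - curve.min())
    scale = 1.0 / crange if crange > 0 else np.nan
    lab = pattern_label(list(spec.directions), dynamic=spec.pattern_class != "flat")
    peak = _truth_peaks(spec)
    k = len(spec.breakpoints)
    return {
        "gene": gene,
        "pattern_class": spec.pattern_class,
        "label": lab.label,
        "onset": lab.onset,
        "k": k,
        "first_breakpoint": spec.breakpoints[0] if k else np.nan,
        "breakpoints": ";".join(f"{b:.6g}" for b in spec.breakpoints),
        "slopes_scaled": ";".join(f"{s * scale:.6g}" for s in spec.slopes),
        "peak_time": peak[0] if peak else np.nan,
        "peak_up_slope_scaled": peak[1] * scale if peak else np.nan,
        "peak_down_slope_scaled": peak[2] * scale if peak else np.nan,
        "point_directions": ";".join(_point_dirs(spec, grid)),
    }


def _point_dirs(spec: PatternSpec, grid: TimeGrid) -> list[str]:
    b = np.asarray(spec.breakpoints)
    seg = np.searchsorted(b, grid.times, side="left")
    dirs = spec.directions
    return [dirs[s] for s in seg]


def _truth_from_specs(specs: dict[str, PatternSpec], grid: TimeGrid) -> GroundTruth:
    rows = [_truth_row(g, s, grid) for g, s in specs.items()]
    return GroundTruth(table=pd.DataFrame(rows).set_index("gene"), specs=specs)


# ---------------------------------------------------------------------------
# public API

def simulate_profiles(config: SimConfig) -> tuple[pd.DataFrame, GroundTruth]:
    """Noise-free scaled mean curves on ``config.grid`` plus ground truth.

    Deterministic in ``config.profile_seed``; independent of ``config.seed``.
    """
    rng = np.random.default_rng(config.profile_seed)
    classes = list(config.pattern_mix)
    probs = np.array([config.pattern_mix[c] for c in classes])
    draws = rng.choice(len(classes), size=config.n_genes, p=probs)
    end = float(config.grid.times[-1])
    specs = {}
    for i, ci in enumerate(draws):
        gene = f"g{i:05d}"
        specs[gene] = _make_spec(rng, classes[ci], end)
    curves = pd.DataFrame(
        np.vstack([specs[g].curve(config.grid.times, end=end) for g in specs]),
        index=list(specs),
        columns=config.grid.sample_ids(),
    )
    return curves, _truth_from_specs(specs, config.grid)


def _dilate_spec(spec: PatternSpec, speedup: float, end: float) -> PatternSpec:
    """Slow a fast-timeline spec down by ``speedup``, truncating events that
    leave the observation window; the terminal segment is extended to the
    window end, its endpoint clipped into the unit band.

    Breakpoint-free specs (monotonic, flat) are returned unchanged: they
    describe trends whose completion lies beyond both observation windows,
    so their within-window amplitude is species-comparable rather than
    time-dilated."""
    if not spec.breakpoints:
        return spec
    s = speedup
    tt, vv = spec.node_values(end)
    b = np.asarray(spec.breakpoints, dtype=float)
    keep = b * s < end - 30.0  # truncated events may not crowd the window edge
    kb = b[keep] * s
    kk = int(keep.sum())
    dirs = list(spec.directions[: kk + 1])
    v_nodes = vv[: kk + 1]
    # linear extension of the last retained segment to the window end
    t_last = kb[-1] if kk else 0.0
    slope_last = spec.slopes[kk] / s
    v_end = float(np.clip(v_nodes[-1] + slope_last * (end - t_last), 0.02, 0.98))
    slopes = [sl / s for sl in spec.slopes[:kk]] + [(v_end - v_nodes[-1]) / (end - t_last)]
    if dirs[-1] == SAME:
        slopes[-1] = 0.0
    lab = pattern_label(dirs, dynamic=any(d != SAME for d in dirs))
    return PatternSpec(
        pattern_class=lab.label,
        breakpoints=tuple(kb.tolist()),
        slopes=tuple(slopes),
        baseline=spec.baseline,
        onset=lab.onset,
    )


def simulate_pair(config: SimConfig) -> SimPair:
    """Paired species-A/species-B profiles sharing gene identities.

    A lives on ``config.grid`` (fast timeline), B on ``config.grid_b``
    with every event time multiplied by ``kinetic_speedup`` and every
    interior slope divided by it.
    """
    profiles_a, truth_a = simulate_profiles(config)
    end_b = float(config.grid_b.times[-1])
    specs_b = {
        g: _dilate_spec(spec, config.kinetic_speedup, end_b)
        for g, spec in truth_a.specs.items()
    }
    profiles_b = pd.DataFrame(
        np.vstack([specs_b[g].curve(config.grid_b.times, end=end_b) for g in specs_b]),
        index=list(specs_b),
        columns=config.grid_b.sample_ids(),
    )
    truth_b = _truth_from_specs(specs_b, config.grid_b)
    return SimPair(profiles_a, truth_a, profiles_b, truth_b, config)


def simulate_counts(
    curves: pd.DataFrame,
    config: SimConfig,
    grid: TimeGrid | None = None,
    seed: int | None = None,
    exact: bool = False,
) -> tuple[CountMatrix, pd.Series]:
    """Observe scaled mean curves as (expected) counts.

    mu_ij = mean_count_scale * (0.1 + 0.9 x_ij), multiplied by a
    log-normal size factor per sample (median-centered to 1, so
    median-ratio normalization is the exact inverse). Counts are NB with
    variance mu + dispersion * mu^2, Poisson when dispersion is 0. With
    ``exact=True`` the expected values themselves are returned (size
    factors 1) — the noiseless limit used by inversion tests.
    """
    grid = grid or config.grid
    x = curves.to_numpy(dtype=float)
    if x.shape[1] != len(grid):
        raise ValueError("curve columns must match grid length")
    if np.any(x < 0) or np.any(x > 1 + 1e-9):
        raise ValueError("scaled curves must lie in [0, 1]")
    mu = config.mean_count_scale * (0.1 + 0.9 * x)
    if exact:
        s = np.ones(x.shape[1])
        counts = mu
    else:
        rng = np.random.default_rng(config.seed if seed is None else seed)
        z = rng.normal(0.0, config.size_factor_sigma, size=x.shape[1])
        s = np.exp(z - np.median(z))
        lam = mu * s[None, :]
        if config.dispersion == 0:
            counts = rng.poisson(lam).astype(float)
        else:
            nb_n = 1.0 / config.dispersion
            counts = rng.negative_binomial(nb_n, nb_n / (nb_n + lam)).astype(float)
    data = pd.DataFrame(counts, index=curves.index, columns=grid.sample_ids())
    factors = pd.Series(s, index=data.columns, name="size_factor")
    return CountMatrix(data=data, grid=grid), factors


def write_ground_truth(truth: GroundTruth, path) -> None:
    truth.table.to_csv(path, sep="\t", index_label="gene")
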