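"""Per-gene segmented (breakpoint) regression with BIC model selection.

Each gene's unit-scaled expression profile x(t) is modeled as a continuous
piecewise-linear function of time,

    x(t) = beta_0 + beta_1 * t + sum_k gamma_k * (t - b_k)_+ ,

so the slope of segment k+1 is beta_1 + gamma_1 + ... + gamma_k and the
fitted curve is continuous at every breakpoint b_k. A sample at exactly
t == b_k belongs to the left segment. For each candidate breakpoint count
K = 0..K_max the breakpoint locations are optimized under the constraint
that every segment contains at least ``min_seg_points`` observed times,
and the best K is chosen by the Bayesian information criterion, counting
the K breakpoint locations as free parameters alongside the K+2 linear
coefficients. Segment directions (up / down / same) come from two-sided
t-tests on the segment slopes in the full segmented design.

The breakpoint optimizer is fully deterministic: a discrete exhaustive
search on small problems (K <= 2, N <= 40), and otherwise a multi-start
Muggeo-style iterative linearization seeded at quantile-spaced positions
and at the best combination from a coarse candidate sweep, finished by
coordinate descent over observed interior times. Ties in RSS are broken
toward the earliest breakpoint times, and ties in BIC toward smaller K.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .grid import TimeGrid
from .preprocess import ScaledMatrix

__all__ = [
    "FitOptions",
    "SegmentedFit",
    "fit_fixed_breakpoints",
    "fit_segmented",
    "brute_force_fit",
    "score_fit",
    "classify_segment_directions",
    "permutation_r2_threshold",
]

UP, DOWN, SAME = "up", "down", "same"


@dataclass(frozen=True)
class FitOptions:
    """Tuning knobs of the segmented fit.

    min_seg_points is 5 on 4-minute grids (a 20-minute minimum segment)
    and 3 on 10-minute grids or week-long series (30 minutes); the
    adjusted-R^2 gate defaults to 0.2 for minute-scale courses and is
    raised to 0.5 for week-long ones.
    """

    max_breakpoints: int = 5
    min_seg_points: int = 5
    direction_alpha: float = 0.2
    r2_threshold: float = 0.2
    n_coarse: int = 12          # candidate positions in the coarse sweep
    cd_window: int = 8          # half-width (grid steps) of coordinate descent
    max_muggeo_iter: int = 30

    def __post_init__(self):
        if self.max_breakpoints < 0:
            raise ValueError("max_breakpoints must be >= 0")
        if self.min_seg_points < 2:
            raise ValueError("min_seg_points must be >= 2")
        if not 0 < self.direction_alpha < 1:
            raise ValueError("direction_alpha must lie in (0, 1)")


@dataclass
class SegmentedFit:
    """Best piecewise-linear model for one gene."""

    K: int
    breakpoints: np.ndarray          # minutes, strictly increasing, interior
    intercept: float
    slopes: np.ndarray               # per-segment slopes, length K+1
    fitted: np.ndarray
    rss: float
    bic: float
    adjusted_r2: float
    segment_p: np.ndarray            # two-sided slope p-values, length K+1
    directions: list[str]            # up / down / same per segment
    point_directions: list[str]      # direction of each sample's segment
    dynamic: bool = False            # adjusted R^2 above the gate
    gene: str | None = None
    by_k: dict = field(default_factory=dict, repr=False)  # K -> (breakpoints, rss, bic)


# ---------------------------------------------------------------------------
# least squares on the hinge basis

def _design(t: np.ndarray, b: np.ndarray) -> np.ndarray:
    cols = [np.ones_like(t), t]
    for bk in b:
        cols.append(np.maximum(t - bk, 0.0))
    return np.column_stack(cols)


def _ols(X: np.ndarray, x: np.ndarray):
    """Solve min ||x - X beta||^2; returns (beta, rss). Robust to rank loss."""
    XtX = X.T @ X
    Xty = X.T @ x
    try:
        beta = np.linalg.solve(XtX, Xty)
    except np.linalg.LinAlgError:
        beta = np.linalg.lstsq(X, x, rcond=None)[0]
    resid = x - X @ beta
    return beta, float(resid @ resid)


def _rss_at(t: np.ndarray, x: np.ndarray, b: np.ndarray) -> float:
    return _ols(_design(t, b), x)[1]


def _seg_counts(t: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Observed points per segment with left-closed membership (t <= b_k)."""
    edges = np.searchsorted(t, b, side="right")
    return np.diff(np.concatenate([[0], edges, [t.size]]))


def _feasible(t: np.ndarray, b: np.ndarray, min_seg: int) -> bool:
    if b.size == 0:
        return t.size >= min_seg
    if np.any(np.diff(b) <= 0):
        return False
    if b[0] < t[0] or b[-1] >= t[-1]:
        return False
    return bool((_seg_counts(t, b) >= min_seg).all())


def _segment_slopes(beta: np.ndarray, K: int) -> np.ndarray:
    # slope of segment k+1 = beta_1 + gamma_1 + ... + gamma_k
    return np.cumsum(np.concatenate([[beta[1]], beta[2 : 2 + K]]))


def score_fit(rss: float, tss: float, n: int, k: int) -> tuple[float, float]:
    """BIC and adjusted R^2 of a fit with k breakpoints on n points.

    The parameter count p = 2 + 2k charges the intercept, the base slope,
    the k hinge coefficients and the k estimated breakpoint locations.
    BIC = n ln(RSS/n) + p ln(n); when RSS is numerically zero it is floored
    to keep the criterion finite while preserving the ordering. Adjusted
    R^2 = 1 - (1 - R^2)(n - 1)/(n - p - 1), reported as NaN when
    n <= p + 1.
    """
    if rss < 0:
        raise ValueError("RSS must be nonnegative")
    p = 2 + 2 * k
    # floor numerically-zero residuals relative to the signal scale so a
    # perfect fit at small K is not outranked by roundoff at larger K
    rss_floor = max(rss, tss * 1e-12, 1e-300)
    bic = n * np.log(rss_floor / n) + p * np.log(n)
    if n <= p + 1 or tss <= 0:
        adj = np.nan
    else:
        r2 = 1.0 - rss / tss
        adj = 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)
    return float(bic), float(adj)


# ---------------------------------------------------------------------------
# breakpoint search for fixed K

def _feasible_index_bounds(N: int, K: int, min_seg: int):
    """Breakpoint k (0-based) placed at index i means b = t[i]; the left
    block then holds indices <= i. Feasible index range for breakpoint k:
    at least (k+1)*min_seg points to the left, (K-k)*min_seg to the right."""
    lo = [min_seg * (k + 1) - 1 for k in range(K)]
    hi = [N - 1 - min_seg * (K - k) for k in range(K)]
    return lo, hi


def _exhaustive_k(t, x, K, min_seg):
    """Exact discrete minimum over breakpoints at observed interior times."""
    N = t.size
    lo, hi = _feasible_index_bounds(N, K, min_seg)
    best = (np.inf, None)
    if K == 1:
        for i in range(lo[0], hi[0] + 1):
            b = t[[i]]
            rss = _rss_at(t, x, b)
            if rss < best[0] - 1e-15:
                best = (rss, b)
    elif K == 2:
        for i in range(lo[0], hi[0] + 1):
            for j in range(i + min_seg, hi[1] + 1):
                b = t[[i, j]]
                rss = _rss_at(t, x, b)
                if rss < best[0] - 1e-15:
                    best = (rss, b)
    else:
        raise ValueError("exhaustive search implemented for K <= 2")
    return best[1], best[0]


def _project_indices(idx: np.ndarray, N: int, K: int, min_seg: int) -> np.ndarray:
    """Clip a vector of breakpoint indices into the feasible lattice."""
    lo, hi = _feasible_index_bounds(N, K, min_seg)
    out = np.sort(idx).astype(int)
    for k in range(K):
        floor = lo[k] if k == 0 else max(lo[k], out[k - 1] + min_seg)
        out[k] = min(max(out[k], floor), hi[k])
    for k in range(K - 1, -1, -1):
        ceil = hi[k] if k == K - 1 else min(hi[k], out[k + 1] - min_seg)
        out[k] = max(min(out[k], ceil), lo[k])
    return out


def _muggeo_refine(t, x, b0, min_seg, max_iter):
    """Iterative linearization: augment the hinge basis with the indicator
    columns -1(t > b_k); the ratio of indicator to hinge coefficients is a
    Newton-type step for each breakpoint. Returns (b, rss) of the best
    feasible iterate (continuous breakpoint locations)."""
    K = b0.size
    N = t.size
    b = b0.astype(float).copy()
    best_b, best_rss = b.copy(), _rss_at(t, x, b)
    step_scale = 1.0
    for _ in range(max_iter):
        U = np.maximum(t[None, :] - b[:, None], 0.0)          # K x N
        V = -(t[None, :] > b[:, None]).astype(float)
        X = np.column_stack([np.ones_like(t), t, U.T, V.T])
        beta, _ = _ols(X, x)
        gamma = beta[2 : 2 + K]
        delta = beta[2 + K :]
        with np.errstate(divide="ignore", invalid="ignore"):
            step = np.where(np.abs(gamma) > 1e-12, delta / gamma, 0.0)
        if not np.all(np.isfinite(step)) or np.all(np.abs(step) < 1e-9):
            break
        b_new = b + step_scale * step
        # keep ordered and inside the observable span, then enforce the
        # minimum-segment rule on observed-point counts
        b_new = np.sort(np.clip(b_new, t[0], t[-1] - 1e-9))
        if not _feasible(t, b_new, min_seg):
            idx = np.searchsorted(t, b_new, side="right") - 1
            idx = _project_indices(idx, N, K, min_seg)
            b_new = t[idx].astype(float)
        rss = _rss_at(t, x, b_new)
        if rss < best_rss - 1e-15:
            best_b, best_rss = b_new.copy(), rss
            step_scale = 1.0
        else:
            step_scale *= 0.5
            if step_scale < 0.1:
                break
        if np.max(np.abs(b_new - b)) < 1e-6:
            break
        b = b_new
    return best_b, best_rss


def _coordinate_descent(t, x, idx0, min_seg, window):
    """Discrete local search over observed times, one breakpoint at a time.

    Candidates are scanned in increasing time order with strict-improvement
    acceptance, so equal-RSS candidates resolve to the earliest time."""
    N = t.size
    K = idx0.size
    idx = _project_indices(idx0.copy(), N, K, min_seg)
    rss = _rss_at(t, x, t[idx])
    for _ in range(4):
        moved = False
        for k in range(K):
            left = idx[k - 1] + min_seg if k else min_seg - 1
            right = idx[k + 1] - min_seg if k < K - 1 else N - 1 - min_seg
            lo = max(left, idx[k] - window) if window else left
            hi = min(right, idx[k] + window) if window else right
            for j in range(lo, hi + 1):
                if j == idx[k]:
                    continue
                trial = idx.copy()
                trial[k] = j
                r = _rss_at(t, x, t[trial])
                if r < rss - 1e-15 or (r < rss + 1e-15 and j < idx[k]):
                    idx, rss, moved = trial, r, True
        if not moved:
            break
    return idx, rss


def _optimize_k(t, x, K, opts: FitOptions):
    """Best breakpoints for fixed K; deterministic. Returns (b, rss)."""
    min_seg = opts.min_seg_points
    N = t.size
    if K == 0:
        return np.empty(0), _rss_at(t, x, np.empty(0))
    if K <= 2 and N <= 40:
        return _exhaustive_k(t, x, K, min_seg)
    if K == 1:
        # cheap enough to enumerate every interior time exactly
        return _exhaustive_k(t, x, K, min_seg)

    lo, hi = _feasible_index_bounds(N, K, min_seg)
    best_b, best_rss = None, np.inf

    def consider(b, rss):
        nonlocal best_b, best_rss
        if rss < best_rss - 1e-15 or (
            rss < best_rss + 1e-15 and best_b is not None and tuple(b) < tuple(best_b)
        ):
            best_b, best_rss = np.asarray(b, dtype=float), rss

    # coarse sweep over evenly spaced candidate indices
    coarse = np.unique(np.linspace(min_seg - 1, N - 1 - min_seg, opts.n_coarse).astype(int))
    for combo in itertools.combinations(coarse, K):
        idx = np.array(combo)
        if np.any(np.diff(idx) < min_seg) or idx[0] < lo[0] or idx[-1] > hi[-1]:
            continue
        consider(t[idx], _rss_at(t, x, t[idx]))
    coarse_best = best_b

    # starts: even quantiles, half-shifted quantiles, best coarse combination
    starts = []
    q = np.linspace(0, N - 1, K + 2)[1:-1]
    starts.append(_project_indices(q.astype(int), N, K, min_seg))
    starts.append(_project_indices((q + (N / (2 * (K + 1)))).astype(int), N, K, min_seg))
    if coarse_best is not None:
        starts.append(np.searchsorted(t, coarse_best, side="right") - 1)

    for s in starts:
        b0 = t[_project_indices(np.asarray(s), N, K, min_seg)].astype(float)
        b_ref, rss_ref = _muggeo_refine(t, x, b0, min_seg, opts.max_muggeo_iter)
        consider(b_ref, rss_ref)
        idx0 = _project_indices(
            np.searchsorted(t, b_ref, side="right") - 1, N, K, min_seg
        )
        idx_cd, rss_cd = _coordinate_descent(t, x, idx0, min_seg, opts.cd_window)
        consider(t[idx_cd], rss_cd)
        # polish the discrete optimum with a final continuous refinement
        b_fin, rss_fin = _muggeo_refine(t, x, t[idx_cd].astype(float), min_seg, 10)
        consider(b_fin, rss_fin)

    return best_b, best_rss


# ---------------------------------------------------------------------------
# public fitting API

def _build_fit(t, x, b, opts: FitOptions, gene=None) -> SegmentedFit:
    K = b.size
    n = t.size
    X = _design(t, b)
    beta, rss = _ols(X, x)
    fitted = X @ beta
    tss = float(np.sum((x - x.mean()) ** 2))
    bic, adj = score_fit(rss, tss, n, K)
    slopes = _segment_slopes(beta, K)

    # per-segment slope t-tests from the full segmented-design covariance
    p_lin = K + 2
    df = n - p_lin
    pvals = np.ones(K + 1)
    # a numerically perfect fit leaves no residual scale to test against;
    # call directions from the slope's total effect over the time span
    degenerate = rss <= max(tss, 1.0) * 1e-16
    effect_tol = 1e-8 * max(1.0, float(np.ptp(x)))
    span = float(t[-1] - t[0])
    if df > 0 and not degenerate:
        sigma2 = rss / df
        try:
            XtX_inv = np.linalg.inv(X.T @ X)
        except np.linalg.LinAlgError:
            XtX_inv = np.linalg.pinv(X.T @ X)
        for k in range(K + 1):
            a = np.zeros(p_lin)
            a[1 : 2 + k] = 1.0
            var = sigma2 * float(a @ XtX_inv @ a)
            if var <= 0:
                pvals[k] = 0.0 if abs(slopes[k]) * span > effect_tol else 1.0
            else:
                tstat = slopes[k] / np.sqrt(var)
                pvals[k] = 2 * stats.t.sf(abs(tstat), df)
    elif degenerate:
        pvals = np.where(np.abs(slopes) * span > effect_tol, 0.0, 1.0)
    else:
        pvals[:] = np.nan

    directions = _directions_from(slopes, pvals, opts.direction_alpha)
    seg_of_point = np.searchsorted(b, t, side="left")  # t <= b_k -> left segment
    point_directions = [directions[s] for s in seg_of_point]
    dynamic = bool(np.isfinite(adj) and adj > opts.r2_threshold)
    return SegmentedFit(
        K=K,
        breakpoints=b.astype(float),
        intercept=float(beta[0]),
        slopes=slopes,
        fitted=fitted,
        rss=rss,
        bic=bic,
        adjusted_r2=adj,
        segment_p=pvals,
        directions=directions,
        point_directions=point_directions,
        dynamic=dynamic,
        gene=gene,
    )


def _directions_from(slopes, pvals, alpha) -> list[str]:
    out = []
    for s, p in zip(slopes, pvals):
        if not np.isfinite(p) or p >= alpha or s == 0:
            out.append(SAME)
        else:
            out.append(UP if s > 0 else DOWN)
    return out


def fit_fixed_breakpoints(x, grid: TimeGrid, b, opts: FitOptions | None = None, gene=None) -> SegmentedFit:
    """Least-squares segmented fit at user-supplied breakpoints."""
    opts = opts or FitOptions()
    t = grid.times
    x = np.asarray(x, dtype=float)
    if x.size != t.size:
        raise ValueError("profile length must equal grid length")
    b = np.sort(np.asarray(b, dtype=float))
    if not _feasible(t, b, opts.min_seg_points):
        raise ValueError(
            f"breakpoints {b.tolist()} violate the {opts.min_seg_points}-point "
            "minimum-segment rule or fall outside the grid"
        )
    return _build_fit(t, x, b, opts, gene=gene)


def fit_segmented(x, grid: TimeGrid, opts: FitOptions | None = None, gene=None) -> SegmentedFit:
    """Fit K = 0..K_max breakpoint models and return the lowest-BIC one.

    K never exceeds floor(N / min_seg_points) - 1, the largest count for
    which every segment can hold the minimum number of observed points.
    Equal BIC resolves to the smaller K. Deterministic for fixed input.
    """
    opts = opts or FitOptions()
    t = grid.times
    x = np.asarray(x, dtype=float)
    if x.size != t.size:
        raise ValueError("profile length must equal grid length")
    if np.any(~np.isfinite(x)):
        raise ValueError("profile contains NaN or infinite values")
    n = t.size
    k_cap = min(opts.max_breakpoints, n // opts.min_seg_points - 1)
    k_cap = max(k_cap, 0)
    tss = float(np.sum((x - x.mean()) ** 2))

    by_k = {}
    best = None
    for K in range(k_cap + 1):
        b, rss = _optimize_k(t, x, K, opts)
        bic, _ = score_fit(rss, tss, n, K)
        by_k[K] = (b, rss, bic)
        if best is None or bic < best[1] - 1e-12:
            best = (K, bic)
    fit = _build_fit(t, x, by_k[best[0]][0], opts, gene=gene)
    fit.by_k = by_k
    return fit


def brute_force_fit(x, grid: TimeGrid, K: int, opts: FitOptions | None = None,
                    max_candidates: int = 200_000) -> SegmentedFit:
    """Verification oracle: exhaustive search over breakpoints placed at
    observed interior times, honoring the minimum-segment rule.

    Deliberately independent of the production optimizer: candidate tuples
    come from itertools and each candidate is scored by a plain lstsq on an
    explicitly assembled design matrix.
    """
    opts = opts or FitOptions()
    t = grid.times
    x = np.asarray(x, dtype=float)
    min_seg = opts.min_seg_points
    N = t.size
    if K == 0:
        X = np.column_stack([np.ones(N), t])
        beta = np.linalg.lstsq(X, x, rcond=None)[0]
        return _build_fit(t, x, np.empty(0), opts)
    positions = range(min_seg - 1, N - min_seg)
    best = (np.inf, None)
    n_seen = 0
    for combo in itertools.combinations(positions, K):
        idx = np.asarray(combo)
        if np.any(np.diff(idx) < min_seg):
            continue
        if N - 1 - idx[-1] < min_seg:
            continue
        n_seen += 1
        if n_seen > max_candidates:
            raise RuntimeError("enumeration budget exceeded")
        b = t[idx].astype(float)
        cols = [np.ones(N), t] + [np.where(t > bk, t - bk, 0.0) for bk in b]
        X = np.column_stack(cols)
        beta, res, rank, _ = np.linalg.lstsq(X, x, rcond=None)
        r = x - X @ beta
        rss = float(r @ r)
        if rss < best[0] - 1e-15:
            best = (rss, b)
    if best[1] is None:
        raise ValueError(f"no feasible breakpoint placement for K={K}")
    return _build_fit(t, x, best[1], opts)


def classify_segment_directions(fit: SegmentedFit, alpha: float = 0.2) -> list[str]:
    """Re-label segments at a different p-value threshold.

    p >= alpha (or an exactly zero slope) gives "same"; otherwise the sign
    of the fitted segment slope decides up vs down.
    """
    return _directions_from(fit.slopes, fit.segment_p, alpha)


def fit_matrix(scaled: ScaledMatrix, opts: FitOptions | None = None) -> dict[str, SegmentedFit]:
    """Fit every gene of a scaled matrix; returns gene id -> SegmentedFit."""
    opts = opts or FitOptions()
    return {
        gene: fit_segmented(scaled.X.loc[gene].to_numpy(dtype=float), scaled.grid, opts, gene=gene)
        for gene in scaled.X.index
    }


def permutation_r2_threshold(
    scaled: ScaledMatrix,
    n_perm: int = 10,
    seed: int = 0,
    opts: FitOptions | None = None,
    alpha: float = 0.05,
) -> tuple[float, np.ndarray]:
    """Calibrate the adjusted-R^2 gate by permutation.

    Each round draws one shared permutation of the sample order, refits
    every gene against the unpermuted times, and records the adjusted R^2
    of the BIC-best model. The recommended cutoff is the (1 - alpha)
    quantile of that null distribution; the full distribution is returned
    alongside. Deterministic given the seed.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    opts = opts or FitOptions()
    rng = np.random.default_rng(seed)
    X = scaled.X.to_numpy(dtype=float)
    if X.shape[0] == 0 or X.shape[1] < 2 * opts.min_seg_points:
        raise ValueError("matrix too small to calibrate")
    null = []
    for _ in range(n_perm):
        perm = rng.permutation(X.shape[1])
        for row in X:
            fit = fit_segmented(row[perm], scaled.grid, opts)
            if np.isfinite(fit.adjusted_r2):
                null.append(fit.adjusted_r2)
    null = np.asarray(null)
    return float(np.quantile(null, 1 - alpha)), null
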