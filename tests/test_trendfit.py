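import numpy as np
import pytest
from scipy import stats

from kinetrend.grid import make_time_grid
from kinetrend.preprocess import ScaledMatrix
from kinetrend.trendfit import (
    FitOptions,
    brute_force_fit,
    classify_segment_directions,
    fit_fixed_breakpoints,
    fit_segmented,
    permutation_r2_threshold,
    score_fit,
)

OPTS3 = FitOptions(min_seg_points=3)


def hinge(t, b0, b1, gammas_breaks):
    x = b0 + b1 * t
    for g, b in gammas_breaks:
        x = x + g * np.maximum(t - b, 0)
    return x


class TestFixedBreakpoints:
    def test_noiseless_inversion(self, human):
        t = human.times
        x = hinge(t, 0.0, 0.01, [(-0.02, 300.0)])
        fit = fit_fixed_breakpoints(x, human, [300.0], OPTS3)
        assert fit.rss < 1e-18
        assert np.allclose(fit.slopes, [0.01, -0.01])

    def test_point_at_breakpoint_belongs_left(self, human):
        t = human.times
        x = hinge(t, 0.0, 0.01, [(-0.02, 300.0)])
        fit = fit_fixed_breakpoints(x, human, [300.0], OPTS3)
        i300 = int(np.where(t == 300)[0][0])
        assert fit.point_directions[i300] == fit.directions[0] == "up"
        assert fit.point_directions[i300 + 1] == fit.directions[1] == "down"

    def test_rss_matches_normal_equations_oracle(self, human, rng):
        t = human.times
        for _ in range(10):
            x = rng.normal(size=t.size)
            b = np.array([150.0, 400.0])
            fit = fit_fixed_breakpoints(x, human, b, OPTS3)
            X = np.column_stack([np.ones_like(t), t, np.maximum(t - 150, 0), np.maximum(t - 400, 0)])
            beta = np.linalg.solve(X.T @ X, X.T @ x)
            rss = float(np.sum((x - X @ beta) ** 2))
            assert fit.rss == pytest.approx(rss, rel=1e-10)

    def test_segment_rule_violation_rejected(self, human):
        with pytest.raises(ValueError):
            fit_fixed_breakpoints(np.zeros(len(human)), human, [10.0], FitOptions(min_seg_points=5))


class TestSegmentedSelection:
    def test_straight_line_selects_k0(self, human):
        x = 0.002 * human.times
        fit = fit_segmented(x, human, OPTS3)
        assert fit.K == 0
        assert fit.slopes[0] == pytest.approx(0.002, rel=1e-9)

    def test_noiseless_v_shape_recovers_vertex(self, mouse):
        t = mouse.times
        x = hinge(t, 0.0, 0.003, [(-0.006, 300.0)])
        fit = fit_segmented(x, mouse, FitOptions(min_seg_points=5))
        assert fit.K == 1
        assert abs(fit.breakpoints[0] - 300.0) <= mouse.interval / 2
        assert fit.directions == ["up", "down"]

    def test_nan_input_rejected(self, human):
        x = np.zeros(len(human))
        x[3] = np.nan
        with pytest.raises(ValueError, match="NaN"):
            fit_segmented(x, human, OPTS3)

    def test_length_mismatch_rejected(self, human):
        with pytest.raises(ValueError):
            fit_segmented(np.zeros(10), human, OPTS3)

    def test_k_capped_by_segment_rule(self, rng):
        # 8 points, min 3 per segment: at most one breakpoint considered
        grid = make_time_grid(10, 70)
        x = rng.normal(size=8)
        fit = fit_segmented(x, grid, FitOptions(min_seg_points=3, max_breakpoints=5))
        assert set(fit.by_k) <= {0, 1}

    def test_continuity_at_breakpoints(self, mouse, rng):
        cfg = FitOptions(min_seg_points=5)
        t = mouse.times
        x = hinge(t, 0.1, 0.004, [(-0.007, 200.0), (0.005, 420.0)]) + rng.normal(0, 0.05, t.size)
        fit = fit_segmented(x, mouse, cfg)

        # evaluate the fitted hinge model on both sides of each breakpoint
        def value(tt):
            v = fit.intercept + fit.slopes[0] * tt
            for k, bk in enumerate(fit.breakpoints):
                extra = fit.slopes[k + 1] - fit.slopes[k]
                v = v + extra * np.maximum(tt - bk, 0)
            return v

        for b in fit.breakpoints:
            assert abs(value(b - 1e-7) - value(b + 1e-7)) < 1e-9

    def test_refit_of_fitted_values_is_stable(self, mouse, rng):
        cfg = FitOptions(min_seg_points=5)
        t = mouse.times
        x = hinge(t, 0.1, 0.005, [(-0.009, 250.0)]) + rng.normal(0, 0.08, t.size)
        fit1 = fit_segmented(x, mouse, cfg)
        fit2 = fit_segmented(fit1.fitted, mouse, cfg)
        assert fit2.K == fit1.K
        assert np.all(np.abs(fit2.breakpoints - fit1.breakpoints) <= mouse.interval / 2)

    def test_first_moving_segment_spans_minimum_window(self, mouse, human, rng):
        # 5 points x 4 min (mouse) and 3 points x 10 min (human): an
        # immediate response must persist for the minimum-segment window
        for grid, min_seg in ((mouse, 5), (human, 3)):
            opts = FitOptions(min_seg_points=min_seg)
            t = grid.times
            x = hinge(t, 0.0, 0.008, [(-0.012, 180.0)]) + rng.normal(0, 0.05, t.size)
            fit = fit_segmented(x, grid, opts)
            if fit.K and fit.directions[0] != "same":
                assert np.sum(t <= fit.breakpoints[0]) >= min_seg


class TestScoring:
    def test_perfect_fit_adjusted_r2_is_one(self):
        bic, adj = score_fit(0.0, 10.0, 61, 1)
        assert adj == pytest.approx(1.0)

    def test_no_better_than_mean_is_negative(self):
        # R^2 = 0 at K = 0: adjusted R^2 = 1 - (n-1)/(n-3) < 0
        _, adj = score_fit(10.0, 10.0, 61, 0)
        assert adj == pytest.approx(1 - 60 / 58)
        assert adj < 0

    def test_bic_penalty_monotone_in_k(self):
        bic1, _ = score_fit(5.0, 10.0, 61, 1)
        bic2, _ = score_fit(5.0, 10.0, 61, 2)
        assert bic1 < bic2

    def test_undefined_adjusted_r2_reported_missing(self):
        _, adj = score_fit(1.0, 2.0, 5, 1)  # n <= p + 1
        assert np.isnan(adj)

    def test_negative_rss_rejected(self):
        with pytest.raises(ValueError):
            score_fit(-1.0, 1.0, 10, 0)


class TestDirections:
    def test_steep_noiseless_up(self, human):
        x = 0.0016 * human.times
        fit = fit_segmented(x, human, OPTS3)
        assert fit.directions[0] == "up"
        assert fit.segment_p[0] < 1e-10

    def test_exactly_flat_is_same(self, human):
        fit = fit_fixed_breakpoints(np.full(len(human), 0.5), human, [], OPTS3)
        assert fit.directions == ["same"]

    def test_p_value_matches_t_oracle(self, human, rng):
        t = human.times
        x = 0.0005 * t + rng.normal(0, 0.3, t.size)
        b = np.array([200.0])
        fit = fit_fixed_breakpoints(x, human, b, OPTS3)
        # independent evaluation: OLS covariance of the hinge design
        X = np.column_stack([np.ones_like(t), t, np.maximum(t - 200, 0)])
        beta, *_ = np.linalg.lstsq(X, x, rcond=None)
        resid = x - X @ beta
        df = t.size - 3
        sigma2 = resid @ resid / df
        cov = sigma2 * np.linalg.inv(X.T @ X)
        for k, a in enumerate(([0, 1, 0], [0, 1, 1])):
            a = np.asarray(a, dtype=float)
            tstat = (a @ beta) / np.sqrt(a @ cov @ a)
            p = 2 * stats.t.sf(abs(tstat), df)
            assert fit.segment_p[k] == pytest.approx(p, abs=1e-8)

    def test_relabel_at_stricter_alpha(self, human, rng):
        t = human.times
        x = 0.0002 * t + rng.normal(0, 0.25, t.size)
        fit = fit_fixed_breakpoints(x, human, [], OPTS3)
        strict = classify_segment_directions(fit, alpha=1e-12)
        assert strict == ["same"]


class TestBruteForce:
    def test_k0_equals_plain_line(self, human, rng):
        x = rng.normal(size=len(human))
        bf = brute_force_fit(x, human, 0, OPTS3)
        ff = fit_fixed_breakpoints(x, human, [], OPTS3)
        assert bf.rss == pytest.approx(ff.rss, rel=1e-12)

    def test_recovers_generating_breakpoint_on_12_points(self):
        grid = make_time_grid(10, 110)
        t = grid.times
        x = hinge(t, 0.0, 0.01, [(-0.02, 60.0)])
        bf = brute_force_fit(x, grid, 1, OPTS3)
        assert bf.breakpoints[0] == pytest.approx(60.0)
        assert bf.rss < 1e-18


class TestPermutationThreshold:
    def _noise_matrix(self, grid, n_genes, rng):
        import pandas as pd

        X = rng.uniform(size=(n_genes, len(grid)))
        df = pd.DataFrame(X, index=[f"g{i}" for i in range(n_genes)], columns=grid.sample_ids())
        return ScaledMatrix(X=df, grid=grid)

    def test_null_calibration_and_determinism(self, small_grid, rng):
        opts = FitOptions(min_seg_points=3, max_breakpoints=2)
        sm = self._noise_matrix(small_grid, 30, rng)
        cut1, null1 = permutation_r2_threshold(sm, n_perm=3, seed=5, opts=opts)
        cut2, _ = permutation_r2_threshold(sm, n_perm=3, seed=5, opts=opts)
        assert cut1 == cut2
        # iid noise: the unpermuted fits are themselves null draws, so the
        # exceedance rate of the 95th-percentile cutoff stays near 5%
        exceed = np.mean(
            [
                fit_segmented(sm.X.loc[g].to_numpy(), small_grid, opts).adjusted_r2 > cut1
                for g in sm.X.index
            ]
        )
        assert exceed <= 0.20

    def test_dynamic_genes_clear_cutoff(self, small_grid, rng):
        import pandas as pd

        opts = FitOptions(min_seg_points=3, max_breakpoints=2)
        t = small_grid.times
        dyn = np.vstack([hinge(t, 0.0, 1 / 290, []), hinge(t, 0.0, 0.012, [(-0.024, 150.0)])])
        dyn = (dyn - dyn.min(1, keepdims=True)) / np.ptp(dyn, 1, keepdims=True)
        sm = ScaledMatrix(
            X=pd.DataFrame(dyn, index=["lin", "peak"], columns=small_grid.sample_ids()),
            grid=small_grid,
        )
        cut, _ = permutation_r2_threshold(sm, n_perm=5, seed=1, opts=opts)
        for g in sm.X.index:
            assert fit_segmented(sm.X.loc[g].to_numpy(), small_grid, opts).adjusted_r2 > cut

    def test_empty_matrix_rejected(self, small_grid):
        import pandas as pd

        sm = ScaledMatrix(X=pd.DataFrame(columns=small_grid.sample_ids()), grid=small_grid)
        with pytest.raises(ValueError):
            permutation_r2_threshold(sm, n_perm=1, seed=0)
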