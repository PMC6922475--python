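import numpy as np
import pandas as pd
import pytest

from kinetrend.compare import (
    control_overlap,
    delta_M,
    delta_P,
    delta_S,
    intron_exon_change,
    load_ortholog_map,
    subsample_every_k,
)
from kinetrend.grid import mouse_grid
from kinetrend.preprocess import CountMatrix
from kinetrend.simulate import SimConfig, simulate_counts, simulate_profiles
from tests.test_patterns import make_fit


class TestDeltaM:
    def test_identical_samples_centered_at_zero(self, rng):
        x = rng.uniform(0, 600, 15)
        est = delta_M(x, x)
        assert est.delta_m == 0
        assert est.ci_low <= 0 <= est.ci_high

    def test_constant_shift_recovered(self, rng):
        a = rng.uniform(0, 300, 20)
        est = delta_M(a, a + 100)
        assert est.delta_m == pytest.approx(100.0)

    def test_shift_equivariance(self, rng):
        # A-relative convention: ΔM is B's shift, positive when A is earlier
        a = rng.uniform(0, 300, 12)
        b = rng.uniform(0, 300, 14)
        e0 = delta_M(a, b)
        e1 = delta_M(a, b + 50)
        assert e1.delta_m == pytest.approx(e0.delta_m + 50)
        assert e1.ci_low == pytest.approx(e0.ci_low + 50)
        assert e1.ci_high == pytest.approx(e0.ci_high + 50)

    def test_paired_and_unpaired_agree_on_pure_shift(self, rng):
        a = rng.uniform(0, 300, 25)
        b = a + 60
        up = delta_M(a, b)
        pp = delta_M(a, b, paired=True)
        assert up.delta_m == pytest.approx(60) == pp.delta_m
        assert pp.paired and not up.paired

    def test_paired_estimate_is_walsh_median(self, rng):
        a = rng.normal(100, 20, 9)
        b = a + rng.normal(30, 10, 9)
        d = b - a
        walsh = [(d[i] + d[j]) / 2 for i in range(9) for j in range(i, 9)]
        est = delta_M(a, b, paired=True)
        assert est.delta_m == pytest.approx(np.median(walsh))

    def test_degenerate_ties_flagged_as_point(self):
        est = delta_M([5.0, 5.0], [5.0, 5.0])
        assert est.ci_low == est.delta_m == est.ci_high == 0

    def test_large_sample_normal_path_brackets_shift(self, rng):
        a = rng.normal(200, 40, 300)
        b = a + 80 + rng.normal(0, 5, 300)
        est = delta_M(a, b, conf=0.99)
        assert est.ci_low < 80 < est.ci_high
        assert est.ci_high - est.ci_low < 30

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            delta_M([], [1.0])
        with pytest.raises(ValueError):
            delta_M([1.0, 2.0], [1.0, 2.0, 3.0], paired=True)


class TestDeltaP:
    def test_equal_proportions(self):
        est = delta_P(50, 100, 50, 100)
        assert est.delta_p_pct == 0
        assert est.ci_low < 0 < est.ci_high

    def test_closed_form_continuity_corrected(self):
        from scipy import stats

        est = delta_P(45, 50, 40, 50, conf=0.99)
        d = 45 / 50 - 40 / 50
        z = stats.norm.ppf(0.995)
        width = z * np.sqrt(0.9 * 0.1 / 50 + 0.8 * 0.2 / 50) + 0.5 * (1 / 50 + 1 / 50)
        assert est.delta_p_pct == pytest.approx(100 * d)
        assert est.ci_low == pytest.approx(100 * (d - width))
        assert est.ci_high == pytest.approx(100 * (d + width))

    def test_boundary_truncated(self):
        est = delta_P(0, 50, 50, 50)
        assert est.delta_p_pct == -100
        assert est.ci_low >= -100 and est.ci_high <= 100

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            delta_P(5, 0, 1, 10)
        with pytest.raises(ValueError):
            delta_P(11, 10, 1, 10)


class TestDeltaS:
    def test_identical_groups_ratio_one(self, rng):
        s = rng.gamma(2, 0.005, 50)
        est = delta_S(s, s, n_boot=500, seed=1)
        assert est.delta_s == pytest.approx(1.0)

    def test_scale_equivariance(self, rng):
        b = rng.gamma(2, 0.005, 60)
        est = delta_S(2 * b, b, n_boot=500, seed=1)
        assert est.delta_s == pytest.approx(2.0)

    def test_sign_invariance_under_magnitudes(self, rng):
        b = rng.gamma(2, 0.005, 60)
        est_pos = delta_S(2 * b, b, n_boot=500, seed=1)
        est_neg = delta_S(-2 * b, -b, n_boot=500, seed=1)
        assert est_neg.delta_s == pytest.approx(est_pos.delta_s)

    def test_deterministic_given_seed(self, rng):
        a, b = rng.gamma(2, 1, 40), rng.gamma(2, 1, 40)
        e1 = delta_S(a, b, n_boot=300, seed=7)
        e2 = delta_S(a, b, n_boot=300, seed=7)
        assert (e1.ci_low, e1.ci_high) == (e2.ci_low, e2.ci_high)

    def test_zero_median_rejected(self):
        with pytest.raises(ValueError):
            delta_S([1.0, 2.0], [0.0, 0.0, 0.0])


class TestSubsample:
    def test_mouse_matrix_every_third(self, rng):
        grid = mouse_grid()
        data = pd.DataFrame(
            rng.poisson(50, size=(3, len(grid))).astype(float),
            index=["a", "b", "c"],
            columns=grid.sample_ids(),
        )
        cm = CountMatrix(data=data, grid=grid)
        out = subsample_every_k(cm, 3)
        assert len(out.grid) == 49
        assert out.grid.interval == 12
        assert out.data.shape == (3, 49)

    def test_k1_identity(self, rng):
        grid = mouse_grid()
        data = pd.DataFrame(
            rng.poisson(50, size=(2, len(grid))).astype(float),
            index=["a", "b"],
            columns=grid.sample_ids(),
        )
        cm = CountMatrix(data=data, grid=grid)
        out = subsample_every_k(cm, 1)
        pd.testing.assert_frame_equal(out.data, cm.data)

    def test_too_coarse_rejected(self, rng):
        grid = mouse_grid()
        data = pd.DataFrame(
            rng.poisson(50, size=(1, len(grid))).astype(float),
            index=["a"],
            columns=grid.sample_ids(),
        )
        with pytest.raises(ValueError):
            subsample_every_k(CountMatrix(data=data, grid=grid), 200)


class TestControlOverlap:
    def test_identical_sets_all_similar(self):
        fits = {f"g{i}": make_fit(["up", "down"], [100.0]) for i in range(5)}
        rep = control_overlap(fits, fits)
        assert rep.n_shared == 5
        assert rep.n_similar == 5 and rep.n_opposite == 0

    def test_flipped_directions_all_opposite(self):
        cond = {f"g{i}": make_fit(["up", "down"], [100.0]) for i in range(4)}
        ctrl = {f"g{i}": make_fit(["down", "up"], [100.0]) for i in range(4)}
        rep = control_overlap(cond, ctrl)
        assert rep.n_opposite == 4 and rep.n_similar == 0

    def test_disjoint_dynamic_sets(self):
        cond = {"g0": make_fit(["up", "down"], [100.0]), "g1": make_fit(["up"], dynamic=False)}
        ctrl = {"g0": make_fit(["up"], dynamic=False), "g1": make_fit(["up", "down"], [50.0])}
        rep = control_overlap(cond, ctrl)
        assert rep.n_shared == 0

    def test_no_shared_ids_rejected(self):
        with pytest.raises(ValueError):
            control_overlap({"a": make_fit(["up"])}, {"b": make_fit(["up"])})


class TestIntronExon:
    def _cm(self, rows):
        grid = mouse_grid()
        df = pd.DataFrame(rows, index=grid.sample_ids()).T
        return CountMatrix(data=df.astype(float), grid=grid)

    def test_constant_gene_zero_change(self):
        grid = mouse_grid()
        cm = self._cm({"a": np.full(len(grid), 7.0), "b": np.arange(len(grid), dtype=float)})
        out, corr = intron_exon_change(cm, cm)
        assert out.loc["a", "delta_exon"] == 0
        assert corr == pytest.approx(1.0)

    def test_linear_gene_closed_form(self):
        grid = mouse_grid()
        t = grid.times
        a = 0.5
        cm = self._cm({"lin": a * t, "other": np.ones(len(grid))})
        out, _ = intron_exon_change(cm, cm, window=10)
        expect = a * (t[-10:].mean() - t[:10].mean())
        assert out.loc["lin", "delta_exon"] == pytest.approx(expect)

    def test_window_too_wide_rejected(self):
        grid = mouse_grid()
        cm = self._cm({"a": np.ones(len(grid))})
        with pytest.raises(ValueError):
            intron_exon_change(cm, cm, window=100)


class TestOrthologMap:
    def test_clean_pairs_kept(self, tmp_path):
        p = tmp_path / "orth.tsv"
        p.write_text("a1\tb1\na2\tb2\n")
        m = load_ortholog_map(p)
        assert m.pairs == (("a1", "b1"), ("a2", "b2"))

    def test_ambiguous_pairs_dropped(self, tmp_path):
        p = tmp_path / "orth.tsv"
        p.write_text("a1\tb1\na1\tb2\na3\tb3\n")
        m = load_ortholog_map(p)
        assert m.pairs == (("a3", "b3"),)
        assert m.n_dropped_ambiguous == 2

    def test_exact_duplicates_collapse(self, tmp_path):
        p = tmp_path / "orth.tsv"
        p.write_text("a1\tb1\na1\tb1\n")
        m = load_ortholog_map(p)
        assert m.pairs == (("a1", "b1"),)

    def test_empty_file_rejected(self, tmp_path):
        p = tmp_path / "orth.tsv"
        p.write_text("")
        with pytest.raises((ValueError, pd.errors.EmptyDataError)):
            load_ortholog_map(p)
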