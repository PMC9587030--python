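"""Cluster-number selection: reference sampling, gap statistics, the 1-SE
rule, Clest, and the three-method consensus."""

import numpy as np
import pytest
from scipy import stats

from phenoclust.kselect import (
    ClestReport,
    GapCurve,
    choose_k_one_se,
    classification_error_rate,
    clest,
    gap_curves,
    gap_statistic,
    make_sparse_clusterer,
    reference_sample,
    select_k_consensus,
)


class TestReferenceSample:
    def test_single_column_uniform_over_range(self, rng):
        x = rng.normal(5, 2, (200, 1))
        R = reference_sample(x, rng)
        assert R.shape == x.shape
        assert R.min() >= x.min() - 1e-9
        assert R.max() <= x.max() + 1e-9

    def test_shape_and_mean_preserved(self, rng):
        X = rng.normal(0, 1, (150, 4)) @ np.diag([3.0, 1.0, 0.5, 0.1])
        R = reference_sample(X, rng)
        assert R.shape == X.shape
        # the box midpoint tracks the column mean up to range asymmetry
        sd = X.std(axis=0)
        assert np.all(np.abs(R.mean(axis=0) - X.mean(axis=0)) < 0.75 * sd + 0.05)

    def test_principal_axis_ranges_approximately_preserved(self, rng):
        X = rng.normal(0, 1, (200, 3)) @ np.diag([4.0, 2.0, 1.0])
        mu = X.mean(axis=0)
        _, _, Vt = np.linalg.svd(X - mu, full_matrices=False)
        R = reference_sample(X, rng)
        Zx = (X - mu) @ Vt.T
        Zr = (R - mu) @ Vt.T
        assert np.all(Zr.min(axis=0) >= Zx.min(axis=0) - 1e-9)
        assert np.all(Zr.max(axis=0) <= Zx.max(axis=0) + 1e-9)

    def test_rotated_coordinates_are_uniform(self, rng):
        X = rng.normal(0, 1, (10000, 3)) @ np.array(
            [[2.0, 0.5, 0.0], [0.0, 1.0, 0.3], [0.0, 0.0, 0.4]]
        )
        mu = X.mean(axis=0)
        _, _, Vt = np.linalg.svd(X - mu, full_matrices=False)
        R = reference_sample(X, rng)
        Z = (R - mu) @ Vt.T
        for j in range(3):
            lo, hi = Z[:, j].min(), Z[:, j].max()
            d, _ = stats.kstest((Z[:, j] - lo) / (hi - lo), "uniform")
            assert d < 0.02

    def test_zero_range_coordinate_is_constant(self, rng):
        X = np.column_stack([rng.normal(0, 1, 50), np.full(50, 2.0)])
        R = reference_sample(X, rng)
        assert np.allclose(R[:, 1], 2.0, atol=1e-9)

    def test_missing_cells_rejected(self, rng):
        X = rng.normal(0, 1, (10, 2))
        X[0, 0] = np.nan
        with pytest.raises(ValueError):
            reference_sample(X, rng)


class TestChooseKOneSE:
    def test_forced_example(self):
        curve = GapCurve(
            k_values=[2, 3, 4],
            gap=np.array([0.50, 0.80, 0.78]),
            se=np.array([0.02, 0.03, 0.05]),
        )
        # 0.50 < 0.80 - 0.03 = 0.77; 0.80 > 0.78 - 0.05 = 0.73 -> k = 3
        assert choose_k_one_se(curve) == 3

    def test_huge_se_selects_smallest_k(self):
        curve = GapCurve(
            k_values=[2, 3, 4, 5],
            gap=np.array([0.1, 0.2, 0.3, 0.4]),
            se=np.array([5.0, 5.0, 5.0, 5.0]),
        )
        assert choose_k_one_se(curve) == 2

    def test_strictly_increasing_tiny_se_returns_none(self):
        curve = GapCurve(
            k_values=[2, 3, 4],
            gap=np.array([0.1, 0.5, 0.9]),
            se=np.array([1e-6, 1e-6, 1e-6]),
        )
        assert choose_k_one_se(curve) is None

    def test_non_contiguous_range_rejected(self):
        curve = GapCurve(k_values=[2, 4], gap=np.zeros(2), se=np.ones(2))
        with pytest.raises(ValueError):
            choose_k_one_se(curve)


class TestGapStatistic:
    def test_reference_drawn_data_gap_near_zero(self, rng):
        """Data drawn from the reference null itself: gap within Monte-Carlo
        error of zero at every k.  (The null matrix is itself a reference
        draw, so its PCA box reproduces its own distribution.)"""
        seed_matrix = rng.normal(0, 1, (80, 4)) @ np.diag([3.0, 2.0, 1.0, 0.5])
        X = reference_sample(seed_matrix, rng)
        clusterer = make_sparse_clusterer(n_start=5)
        gap, wgap = gap_curves(X, range(2, 5), 50, clusterer, seed=rng)
        for c in (gap, wgap):
            assert np.all(np.abs(c.gap) < 3.5 * np.maximum(c.se, 0.03))

    def test_three_blob_recovery(self, blobs3):
        X, _ = blobs3
        clusterer = make_sparse_clusterer(n_start=10)
        hits = 0
        for s in range(8):
            gap, _ = gap_curves(X, range(2, 6), 25, clusterer, seed=300 + s)
            hits += gap.chosen_k == 3
        assert hits >= 7

    def test_weighted_flag_selects_curve(self, blobs3):
        X, _ = blobs3
        clusterer = make_sparse_clusterer(n_start=5)
        wg = gap_statistic(X, range(2, 4), 10, clusterer, weighted=True, seed=0)
        assert wg.weighted

    def test_singleton_clusters_raise(self):
        rng = np.random.default_rng(0)
        X = rng.normal(0, 1, (6, 2))
        clusterer = make_sparse_clusterer(n_start=3)
        with pytest.raises(ValueError):
            gap_curves(X, range(5, 7), 5, clusterer, seed=1)

    def test_b_ref_lower_bound(self, blobs3):
        X, _ = blobs3
        with pytest.raises(ValueError):
            gap_curves(X, range(2, 4), 1, make_sparse_clusterer(), seed=0)

    def test_gap_equals_wgap_shift_on_balanced_toy(self):
        """On equal-sized clusters the two dispersions differ by the constant
        1/(n_r - 1), so the curves differ by a k-dependent deterministic
        shift; with equal sizes across clusters log Wbar = log W - log(n_r-1)."""
        from phenoclust.kselect import _pooled_dispersions
        from phenoclust.spkmeans import ClusterSolution

        rng = np.random.default_rng(5)
        X = np.vstack([rng.normal(-3, 1, (20, 2)), rng.normal(3, 1, (20, 2))])
        labels = np.repeat([0, 1], 20)
        sol = ClusterSolution(
            labels=labels, weights=np.ones(2) / np.sqrt(2), centers=np.zeros((2, 2)),
            objective=0.0, k=2, l=np.sqrt(2),
        )
        W, Wbar = _pooled_dispersions(X, sol)
        assert np.log(Wbar) == pytest.approx(np.log(W) - np.log(19), abs=1e-10)


class TestClest:
    def test_cer_bounds_after_matching(self, rng):
        a = rng.integers(0, 3, 60)
        b = rng.integers(0, 3, 60)
        cer = classification_error_rate(a, b)
        assert 0.0 <= cer <= 2 / 3

    def test_identical_partitions_zero_error(self, rng):
        a = rng.integers(0, 4, 40)
        relabel = np.array([2, 3, 0, 1])
        assert classification_error_rate(a, relabel[a]) == 0.0

    def test_adjusted_statistic_formulas(self):
        """d_k and p_k follow directly from the observed and reference rates."""
        report = ClestReport(k_values=[2])
        report.t_obs[2] = 0.10
        t0 = np.array([0.25, 0.30, 0.35, 0.40])
        sd = t0.std(ddof=1)
        d = (t0.mean() - 0.10) / sd
        assert d == pytest.approx((0.325 - 0.10) / sd)
        assert np.mean(t0 <= 0.10) == 0.0

    def test_structured_data_chooses_three(self, blobs3):
        X, _ = blobs3
        clusterer = make_sparse_clusterer(n_start=5)
        rep = clest(X, range(2, 5), clusterer, B_obs=30, B_ref=12, B_ref_splits=12, seed=11)
        assert rep.chosen_k == 3

    def test_null_box_data_mostly_no_significant_k(self):
        """Structureless data drawn from the reference family itself: no k
        should be declared significant in most runs."""
        clusterer = make_sparse_clusterer(n_start=5)
        none_count = 0
        n_rep = 6
        for s in range(n_rep):
            r = np.random.default_rng(50 + s)
            seed_matrix = r.normal(0, 1, (60, 4)) @ np.diag([3.0, 2.0, 1.0, 0.5])
            X = reference_sample(seed_matrix, r)
            rep = clest(X, range(2, 5), clusterer, B_obs=16, B_ref=20, B_ref_splits=10, seed=s)
            none_count += rep.chosen_k is None
        assert none_count >= n_rep - 1

    def test_bad_train_fraction_rejected(self, blobs3):
        X, _ = blobs3
        with pytest.raises(ValueError):
            clest(X, [2], make_sparse_clusterer(), train_fraction=1.2)


class TestConsensus:
    def _gap(self, k):
        return GapCurve(k_values=[2, 3, 4], gap=np.zeros(3), se=np.ones(3), chosen_k=k)

    def _clest(self, k):
        return ClestReport(k_values=[2, 3, 4], chosen_k=k)

    def test_unanimous(self):
        out = select_k_consensus(self._gap(3), self._gap(3), self._clest(3))
        assert out["chosen_k"] == 3 and out["consensus"] == "unanimous"

    def test_two_of_three_with_abstention(self):
        out = select_k_consensus(self._gap(3), self._gap(3), self._clest(None))
        assert out["chosen_k"] == 3 and out["consensus"] == "2-of-3"

    def test_three_way_disagreement_flags_no_consensus(self):
        out = select_k_consensus(self._gap(2), self._gap(3), self._clest(4))
        assert out["chosen_k"] is None and out["consensus"] == "disagreement"

    def test_mismatched_ranges_rejected(self):
        short = GapCurve(k_values=[2, 3], gap=np.zeros(2), se=np.ones(2))
        with pytest.raises(ValueError):
            select_k_consensus(short, self._gap(3), self._clest(3))
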