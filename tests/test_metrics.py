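"""Distortion statistics: hand-computed examples, oracles, and invariants."""

import numpy as np
import pytest
import scipy.stats
from hypothesis import given, strategies as st

import embaudit as ea
from embaudit import metrics as M
from embaudit.containers import TypeDistanceMatrix, ValidationError

from oracles import brute_equidistant_groups, brute_knn


def _random_points(seed, n=20, d=3):
    return np.random.default_rng(seed).normal(size=(n, d))


class TestKnnIndex:
    def test_three_collinear_points(self):
        pts = np.array([[0.0], [1.0], [10.0]])
        idx = ea.knn_index(pts, 1)
        assert list(idx.neighbor_idx[:, 0]) == [1, 0, 1]

    def test_l1_equals_l2_in_1d(self):
        pts = _random_points(0, n=25, d=1)
        a = ea.knn_index(pts, 5, "L1")
        b = ea.knn_index(pts, 5, "L2")
        assert np.array_equal(a.neighbor_idx, b.neighbor_idx)

    def test_duplicate_points_are_mutual_nearest(self):
        pts = np.array([[0.0, 0.0], [0.0, 0.0], [5.0, 5.0]])
        idx = ea.knn_index(pts, 1)
        assert idx.neighbor_idx[0, 0] == 1
        assert idx.neighbor_idx[1, 0] == 0
        assert idx.neighbor_dists[0, 0] == 0.0

    def test_k_too_large(self):
        with pytest.raises(ValidationError):
            ea.knn_index(np.zeros((5, 2)), 5)

    @given(st.integers(0, 1000), st.sampled_from(["L1", "L2"]))
    def test_matches_brute_force(self, seed, metric):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(6, 25))
        pts = rng.normal(size=(n, int(rng.integers(1, 5))))
        k = int(rng.integers(1, n - 1))
        idx = ea.knn_index(pts, k, metric)
        oidx, odists = brute_knn(pts, k, metric)
        assert np.array_equal(idx.neighbor_idx, oidx)
        assert np.allclose(idx.neighbor_dists, odists)

    def test_precomputed_distances_agree(self):
        pts = _random_points(3, n=30)
        D = M.pairwise_dists(pts)
        a = ea.knn_index(pts, 4)
        b = ea.knn_index(pts, 4, dists=D)
        assert np.array_equal(a.neighbor_idx, b.neighbor_idx)


class TestJaccard:
    def test_identical_indices_give_zero(self):
        idx = ea.knn_index(_random_points(1), 5)
        assert np.all(ea.jaccard_neighbor_distance(idx, idx) == 0.0)

    @staticmethod
    def _index_from_rows(rows):
        from embaudit.containers import NeighborIndex

        rows = np.asarray(rows)
        n, k = rows.shape
        return NeighborIndex(
            k=k, metric="L2", neighbor_idx=rows,
            neighbor_dists=np.tile(np.arange(1.0, k + 1.0), (n, 1)),
            cell_ids=[f"c{i}" for i in range(n)])

    def test_disjoint_sets_give_one(self):
        n = 8
        a = self._index_from_rows([[(i + 1) % n, (i + 2) % n] for i in range(n)])
        b = self._index_from_rows([[(i + 3) % n, (i + 4) % n] for i in range(n)])
        assert np.all(ea.jaccard_neighbor_distance(a, b) == 1.0)

    def test_hand_computed_half_overlap(self):
        # per cell: A = {i+1, i+2, i+3}, B = {i+2, i+3, i+4} → 1 − 2/4 = 0.5
        n = 6
        a = self._index_from_rows(
            [[(i + 1) % n, (i + 2) % n, (i + 3) % n] for i in range(n)])
        b = self._index_from_rows(
            [[(i + 2) % n, (i + 3) % n, (i + 4) % n] for i in range(n)])
        assert np.allclose(ea.jaccard_neighbor_distance(a, b), 0.5)

    def test_scale_invariance(self):
        pts = _random_points(7, n=40)
        a = ea.knn_index(pts, 6)
        b = ea.knn_index(pts * 13.7, 6)
        assert np.all(ea.jaccard_neighbor_distance(a, b) == 0.0)

    def test_mismatched_k_rejected(self):
        pts = _random_points(2)
        with pytest.raises(ValidationError):
            ea.jaccard_neighbor_distance(ea.knn_index(pts, 3), ea.knn_index(pts, 4))


class TestTypeDistanceMatrix:
    def test_two_types_enumerable_by_hand(self):
        pts = np.array([[0.0], [0.0], [3.0], [3.0]])
        labels = ["a", "a", "b", "b"]
        tdm = ea.type_distance_matrix(pts, labels)
        assert tdm.values[0, 1] == pytest.approx(3.0)
        assert tdm.values[0, 0] == pytest.approx(0.0)
        assert tdm.values[1, 1] == pytest.approx(0.0)

    def test_permutation_invariance(self):
        pts = _random_points(4, n=30)
        labels = np.array(["t%d" % (i % 3) for i in range(30)], dtype=object)
        perm = np.random.default_rng(0).permutation(30)
        a = ea.type_distance_matrix(pts, labels)
        b = ea.type_distance_matrix(pts[perm], labels[perm])
        assert np.allclose(a.values, b.values)

    def test_homogeneity_under_scaling(self):
        pts = _random_points(5, n=24)
        labels = ["t%d" % (i % 4) for i in range(24)]
        a = ea.type_distance_matrix(pts, labels)
        b = ea.type_distance_matrix(pts * 2.5, labels)
        assert np.allclose(b.values, 2.5 * a.values)

    def test_singleton_type_excluded(self):
        pts = _random_points(6, n=7)
        labels = ["a", "a", "a", "b", "b", "b", "c"]
        with pytest.warns(UserWarning, match="singleton"):
            tdm = ea.type_distance_matrix(pts, labels)
        assert list(tdm.labels) == ["a", "b"]


class TestTypeRankingCorrelation:
    def _tdm(self, values):
        values = np.asarray(values, dtype=float)
        labels = [chr(65 + i) for i in range(values.shape[0])]
        return TypeDistanceMatrix(labels=labels, values=values)

    def test_self_comparison_is_one(self):
        ref = ea.type_distance_matrix(_random_points(8, 20), ["t%d" % (i % 4) for i in range(20)])
        assert np.allclose(ea.type_ranking_correlation(ref, ref), 1.0)

    def test_reciprocal_entries_reverse_rankings(self):
        vals = np.array([[0.0, 1.0, 2.0, 3.0],
                         [1.0, 0.0, 4.0, 5.0],
                         [2.0, 4.0, 0.0, 6.0],
                         [3.0, 5.0, 6.0, 0.0]])
        recip = vals.copy()
        off = ~np.eye(4, dtype=bool)
        recip[off] = 1.0 / recip[off]
        rho = ea.type_ranking_correlation(self._tdm(vals), self._tdm(recip))
        assert np.allclose(rho, -1.0)

    def test_hand_swapped_ranks_give_half(self):
        # type A ranks (B,C,D) in ref and (C,B,D) in test → Spearman 0.5
        ref = self._tdm([[0, 1, 2, 3], [1, 0, 9, 9], [2, 9, 0, 9], [3, 9, 9, 0]])
        test = self._tdm([[0, 2, 1, 3], [2, 0, 9, 9], [1, 9, 0, 9], [3, 9, 9, 0]])
        rho = ea.type_ranking_correlation(ref, test)
        assert rho[0] == pytest.approx(0.5)

    def test_fewer_than_three_types_rejected(self):
        two = self._tdm([[0.0, 1.0], [1.0, 0.0]])
        with pytest.raises(ValidationError):
            ea.type_ranking_correlation(two, two)


class TestEquidistantGroups:
    def test_regular_simplex_is_one_group(self):
        pts = ea.generate_equidistant_simplex(5, 8, scale=2.0)
        D = M.pairwise_dists(pts)
        groups = ea.find_equidistant_groups(D, 2.0, 0.01)
        assert groups.groups == [(0, 1, 2, 3, 4)]

    def test_collinear_points_no_group(self):
        pts = np.array([[0.0], [1.0], [3.0]])
        D = M.pairwise_dists(pts)
        groups = ea.find_equidistant_groups(D, 1.0, 0.05)
        assert len(groups) == 0

    @given(st.integers(0, 500))
    def test_matches_brute_force_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        pts = rng.random((15, 2))
        D = M.pairwise_dists(pts)
        iu = np.triu_indices(15, k=1)
        target = float(np.median(D[iu]))
        got = ea.find_equidistant_groups(D, target, 0.25)
        expected = brute_equidistant_groups(D, target, 0.25)
        assert got.groups == expected

    def test_band_invariant_holds(self):
        rng = np.random.default_rng(12)
        pts = rng.random((25, 3))
        D = M.pairwise_dists(pts)
        target = float(np.quantile(D[np.triu_indices(25, 1)], 0.5))
        eps = 0.2
        groups = ea.find_equidistant_groups(D, target, eps)
        for g in groups.groups:
            sub = D[np.ix_(g, g)][np.triu_indices(len(g), 1)]
            assert np.all(sub >= target * (1 - eps) - 1e-12)
            assert np.all(sub <= target * (1 + eps) + 1e-12)

    def test_limit_and_determinism(self):
        rng = np.random.default_rng(13)
        pts = rng.random((30, 2))
        D = M.pairwise_dists(pts)
        target = float(np.median(D[np.triu_indices(30, 1)]))
        a = ea.find_equidistant_groups(D, target, 0.3, limit=5)
        b = ea.find_equidistant_groups(D, target, 0.3, limit=5)
        assert a.groups == b.groups
        assert len(a) <= 5


class TestMaxMinRatio:
    def test_equilateral_triangle(self):
        pts = ea.generate_equidistant_simplex(3, 2)
        assert ea.max_min_ratio(pts, [0, 1, 2]) == pytest.approx(1.0)

    def test_collinear_hand_enumeration(self):
        pts = np.array([[0.0], [1.0], [3.0]])
        assert ea.max_min_ratio(pts, [0, 1, 2]) == pytest.approx(3.0)

    def test_two_point_group(self):
        pts = _random_points(1, n=5)
        assert ea.max_min_ratio(pts, [0, 3]) == pytest.approx(1.0)

    def test_coincident_points_flagged_infinite(self):
        pts = np.array([[0.0, 0.0], [0.0, 0.0], [1.0, 1.0]])
        with pytest.warns(UserWarning, match="coincident"):
            assert np.isinf(ea.max_min_ratio(pts, [0, 1, 2]))

    def test_scale_invariance(self):
        pts = _random_points(14, n=10)
        g = [0, 2, 5, 7]
        assert ea.max_min_ratio(pts, g) == pytest.approx(
            ea.max_min_ratio(pts * 9.0, g))


class TestRatioDistortion:
    def test_identity_space_gives_unit_folds(self):
        pts = _random_points(15, n=20)
        D = M.pairwise_dists(pts)
        target = float(np.median(D[np.triu_indices(20, 1)]))
        groups = ea.find_equidistant_groups(D, target, 0.3)
        if len(groups) == 0:
            pytest.skip("no groups in band for this instance")
        folds, summary = ea.ratio_distortion(groups, pts, pts)
        assert np.allclose(folds, 1.0)
        assert set(summary.columns) == {"size", "count", "median", "mean"}

    def test_scaling_is_ratio_free(self):
        pts = _random_points(16, n=20)
        D = M.pairwise_dists(pts)
        target = float(np.median(D[np.triu_indices(20, 1)]))
        groups = ea.find_equidistant_groups(D, target, 0.3)
        if len(groups) == 0:
            pytest.skip("no groups in band for this instance")
        folds, _ = ea.ratio_distortion(groups, pts, pts * 2.0)
        assert np.allclose(folds, 1.0)

    def test_simplex_projection_inflates_ratio(self):
        # 5 points cannot stay equidistant in the plane
        pts = ea.generate_equidistant_simplex(5, 4)
        rng = np.random.default_rng(17)
        basis, _ = np.linalg.qr(rng.normal(size=(4, 2)))
        proj = pts @ basis
        groups = ea.EquidistantGroupSet([(0, 1, 2, 3, 4)], 1.0, 0.01)
        folds, _ = ea.ratio_distortion(groups, pts, proj)
        assert folds[0] > 1.0


class TestMixingFractions:
    def test_single_condition_all_ones(self):
        pts = _random_points(18, n=15)
        idx = ea.knn_index(pts, 4)
        frac = ea.mixing_fractions(idx, ["only"] * 15)
        assert np.all(frac == 1.0)

    def test_alternating_1d_labels(self):
        pts = np.arange(10.0)[:, None]
        labels = np.array(["a", "b"] * 5, dtype=object)
        idx = ea.knn_index(pts, 2)
        frac = ea.mixing_fractions(idx, labels)
        assert np.all(frac[1:-1] == 0.0)

    def test_separated_batches_unmixed(self):
        pts = np.vstack([_random_points(19, 20, 2), _random_points(20, 20, 2) + 100.0])
        labels = ["x"] * 20 + ["y"] * 20
        idx = ea.knn_index(pts, 5)
        assert np.all(ea.mixing_fractions(idx, labels) == 1.0)

    def test_restrict_label(self):
        pts = _random_points(21, n=12)
        labels = np.array(["p"] * 6 + ["q"] * 6, dtype=object)
        idx = ea.knn_index(pts, 3)
        frac = ea.mixing_fractions(idx, labels, restrict_label="q")
        assert frac.shape == (6,)


class TestKnnLabelPredict:
    def test_perfectly_separable(self):
        pts = np.vstack([_random_points(22, 60, 3), _random_points(23, 60, 3) + 50.0])
        labels = ["a"] * 60 + ["b"] * 60
        acc = ea.knn_label_predict(pts, labels, k=10, seed=0)
        assert acc == 1.0

    def test_random_labels_near_chance(self):
        rng = np.random.default_rng(24)
        pts = rng.normal(size=(1000, 5))
        labels = rng.choice(["a", "b"], size=1000)
        accs = [ea.knn_label_predict(pts, labels, k=50, seed=s) for s in range(10)]
        assert abs(np.mean(accs) - 0.5) < 0.05

    def test_k_reduced_with_warning(self):
        pts = _random_points(25, n=40)
        labels = ["a"] * 36 + ["b"] * 4
        with pytest.warns(UserWarning, match="reducing"):
            acc = ea.knn_label_predict(pts, labels, k=20, seed=0)
        assert 0.0 <= acc <= 1.0

    def test_k_at_least_training_size_rejected(self):
        pts = _random_points(26, n=20)
        with pytest.raises(ValidationError):
            ea.knn_label_predict(pts, ["a", "b"] * 10, k=14, seed=0)


class TestInterIntraKS:
    def test_identical_pools_zero(self):
        assert M._ks_statistic(np.arange(10.0), np.arange(10.0)) == 0.0

    def test_disjoint_supports_one(self):
        rng = np.random.default_rng(27)
        inter = rng.uniform(10, 11, 50)
        intra = rng.uniform(0, 1, 50)
        assert M._ks_statistic(inter, intra) == 1.0

    def test_hand_computed_ecdf_supremum(self):
        assert M._ks_statistic(np.array([1.0, 2.0]),
                               np.array([1.5, 2.5])) == pytest.approx(0.5)

    @given(st.integers(0, 300))
    def test_matches_scipy_on_random_pools(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.normal(size=rng.integers(3, 30))
        b = rng.normal(loc=rng.uniform(-1, 1), size=rng.integers(3, 30))
        mine = M._ks_statistic(a, b)
        assert mine == pytest.approx(scipy.stats.ks_2samp(a, b).statistic)

    def test_full_interface_on_labeled_points(self):
        rng = np.random.default_rng(28)
        pts = np.vstack([rng.normal(size=(30, 2)), rng.normal(size=(30, 2)) + 8.0])
        labels = ["a"] * 30 + ["b"] * 30
        stat, inter, intra = ea.inter_intra_ks(pts, labels)
        assert stat > 0.9
        assert inter.size == 30 * 30
        assert intra.size == 2 * (30 * 29 // 2)


class TestInterIntraCorrelation:
    def _labeled_cloud(self, seed, n_types=5, per=8, d=6):
        rng = np.random.default_rng(seed)
        centers = rng.normal(scale=10.0, size=(n_types, d))
        pts = np.vstack([rng.normal(size=(per, d)) + c for c in centers])
        labels = np.repeat([f"t{i}" for i in range(n_types)], per)
        return pts, np.asarray(labels, dtype=object)

    def test_self_comparison(self):
        pts, labels = self._labeled_cloud(29)
        inter, intra = ea.inter_intra_correlation(pts, pts, labels)
        assert inter == pytest.approx(1.0)
        assert intra == pytest.approx(1.0)

    def test_scale_invariance(self):
        pts, labels = self._labeled_cloud(30)
        inter, intra = ea.inter_intra_correlation(pts * 2.0, pts, labels)
        assert inter == pytest.approx(1.0)
        assert intra == pytest.approx(1.0)

    def test_permutation_null_near_zero(self):
        pts, labels = self._labeled_cloud(31, n_types=20, per=5)
        tdm = ea.type_distance_matrix(pts, labels)
        off = tdm.off_diagonal()
        rng = np.random.default_rng(0)
        corrs = [scipy.stats.pearsonr(off, rng.permutation(off)).statistic
                 for _ in range(100)]
        assert np.mean(np.abs(corrs)) < 0.3


class TestRelativeContrast:
    def test_equal_distances_give_zero(self):
        pts = np.array([[0.0, 0.0], [1.0, 0.0], [-1.0, 0.0]])
        rc = ea.relative_contrast(pts, query_count=3, seed=0)
        assert np.min(rc) == pytest.approx(0.0)  # the origin's two neighbors tie

    def test_hand_computed_values(self):
        pts = np.array([[0.0], [1.0], [3.0]])
        rc = ea.relative_contrast(pts, query_count=3, seed=1)
        assert sorted(np.round(rc, 9)) == [0.5, 1.0, 2.0]

    def test_duplicate_query_resampled(self):
        pts = np.array([[0.0, 0.0], [0.0, 0.0], [1.0, 0.0], [2.0, 0.0]])
        # seed 0 visits a duplicated point before filling the query quota
        with pytest.warns(UserWarning, match="duplicates"):
            rc = ea.relative_contrast(pts, query_count=2, seed=0)
        assert np.all(np.isfinite(rc))

    def test_l1_contrast_beats_l2_in_high_dimension(self):
        logs = []
        for seed in range(5):
            pts = ea.generate_uniform_points(500, 1000, seed=seed)
            rc1 = ea.relative_contrast(pts, 50, norm_order=1, seed=seed)
            rc2 = ea.relative_contrast(pts, 50, norm_order=2, seed=seed)
            logs.append(np.log2(rc1 / rc2).mean())
        assert np.mean(logs) > 0.0


class TestHVGContrastProtocol:
    def test_degenerate_sampling_repeats_values(self, small_lognorm):
        # subset_size == pool_size → every subset is the whole pool, so the
        # n_subsets blocks of per-query ratios are identical
        lognorm, _ = small_lognorm
        out = ea.hvg_subset_contrast_protocol(lognorm, n_subsets=3,
                                              subset_size=100, pool_size=100,
                                              query_count=10, seed=0)
        assert out.shape == (30,)
        blocks = out.reshape(3, 10)
        assert np.array_equal(blocks[0], blocks[1])
        assert np.array_equal(blocks[0], blocks[2])

    def test_output_length_bookkeeping(self, small_lognorm):
        lognorm, _ = small_lognorm
        out = ea.hvg_subset_contrast_protocol(lognorm, n_subsets=4,
                                              subset_size=80, pool_size=150,
                                              query_count=7, seed=1)
        assert out.shape == (28,)

    def test_pool_larger_than_genes_rejected(self, small_lognorm):
        lognorm, _ = small_lognorm
        with pytest.raises(ValidationError):
            ea.hvg_subset_contrast_protocol(lognorm, pool_size=10**6)

    def test_median_positive_on_mixture(self, small_lognorm):
        lognorm, _ = small_lognorm
        out = ea.hvg_subset_contrast_protocol(lognorm, n_subsets=3,
                                              subset_size=150, pool_size=250,
                                              query_count=20, seed=2)
        assert np.median(out) > 0.0


class TestJLMinDimension:
    def test_printed_reference_values(self):
        assert ea.jl_min_dimension(10000, 0.2)[1] == 1842
        assert ea.jl_min_dimension(100, 0.2)[1] == 921

    def test_monotonicity(self):
        b1, _ = ea.jl_min_dimension(1000, 0.2)
        b2, _ = ea.jl_min_dimension(2000, 0.2)
        b3, _ = ea.jl_min_dimension(1000, 0.3)
        assert b2 > b1 > b3

    def test_domain_validation(self):
        with pytest.raises(ValidationError):
            ea.jl_min_dimension(10, 1.5)
        with pytest.raises(ValidationError):
            ea.jl_min_dimension(1, 0.2)
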