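import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial.distance import jaccard as scipy_jaccard

from dartpop.ordination import (
    DistanceMatrix,
    flag_outliers,
    jaccard_distance,
    marker_group_association,
    pca,
    pcoa,
    top_loading_markers,
)
from conftest import make_matrix, random_matrix


class TestJaccard:
    def test_identical_profiles_distance_zero(self):
        d = jaccard_distance(make_matrix([[1, 0, 1], [1, 0, 1]]))
        assert d.values[0, 1] == 0.0

    def test_hand_counted_example(self):
        # profiles (1,1,0,0) vs (1,0,1,0): M11=1, M10=1, M01=1 -> 2/3
        d = jaccard_distance(make_matrix([[1, 1, 0, 0], [1, 0, 1, 0]]))
        assert np.isclose(d.values[0, 1], 2.0 / 3.0)

    def test_disjoint_band_sets_distance_one(self):
        d = jaccard_distance(make_matrix([[1, 1, 0], [0, 0, 1]]))
        assert d.values[0, 1] == 1.0

    def test_matches_scipy_on_complete_data(self, rng):
        mat = random_matrix(rng, 12, 40, missing_rate=0.0)
        d = jaccard_distance(mat).values
        for i in range(12):
            for j in range(i + 1, 12):
                ref = scipy_jaccard(mat.scores[i].astype(bool), mat.scores[j].astype(bool))
                assert np.isclose(d[i, j], ref)

    def test_double_absence_ignored_not_zero_filled(self):
        # double absences must not dilute the distance
        a = jaccard_distance(make_matrix([[1, 0], [0, 1]]))
        b = jaccard_distance(make_matrix([[1, 0, 0, 0], [0, 1, 0, 0]]))
        assert a.values[0, 1] == b.values[0, 1] == 1.0

    def test_no_comparable_informative_marker_is_missing(self):
        with pytest.warns(UserWarning, match="no informative"):
            d = jaccard_distance(make_matrix([[1, -1, 0], [-1, 0, 0]]))
        assert np.isnan(d.values[0, 1])

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(0, 10**6))
    def test_metric_properties_on_complete_panels(self, seed):
        rng = np.random.default_rng(seed)
        mat = random_matrix(rng, 6, 25, missing_rate=0.0)
        d = jaccard_distance(mat).values
        assert np.allclose(d, d.T) and np.allclose(np.diag(d), 0.0)
        n = d.shape[0]
        for i in range(n):
            for j in range(n):
                for k in range(n):
                    if not (np.isnan(d[i, j]) or np.isnan(d[i, k]) or np.isnan(d[k, j])):
                        assert d[i, j] <= d[i, k] + d[k, j] + 1e-12


class TestPCoA:
    def test_equilateral_triangle(self):
        d = DistanceMatrix(["a", "b", "c"], 1.0 - np.eye(3))
        res = pcoa(d, 2)
        assert np.allclose(res.explained_fraction, [0.5, 0.5])
        c = res.coordinates
        pair = [np.linalg.norm(c[i] - c[j]) for i, j in [(0, 1), (0, 2), (1, 2)]]
        np.testing.assert_allclose(pair, pair[0], atol=1e-9)

    def test_line_ordering_recovered(self):
        x = np.array([0.0, 1.0, 3.0, 7.0, 8.0])
        d = DistanceMatrix([f"p{i}" for i in range(5)], np.abs(x[:, None] - x[None, :]))
        res = pcoa(d, 1)
        axis = res.coordinates[:, 0]
        assert np.array_equal(np.argsort(axis), np.argsort(x)) or np.array_equal(
            np.argsort(-axis), np.argsort(x)
        )

    def test_euclidean_distances_reproduce_pca_scores(self, rng):
        pts = rng.normal(size=(15, 3))
        dmat = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
        res = pcoa(DistanceMatrix([f"p{i}" for i in range(15)], dmat), 3)
        centered = pts - pts.mean(axis=0)
        u, s, vt = np.linalg.svd(centered, full_matrices=False)
        scores = u * s
        for ax in range(3):
            r = abs(np.corrcoef(res.coordinates[:, ax], scores[:, ax])[0, 1])
            assert r > 1 - 1e-9

    def test_matches_skbio_eigenvalues(self, rng):
        from skbio.stats.ordination import pcoa as skbio_pcoa
        mat = random_matrix(rng, 10, 60, missing_rate=0.0)
        d = jaccard_distance(mat)
        ours = pcoa(d, 3)
        ref = skbio_pcoa(d.values, number_of_dimensions=3)
        np.testing.assert_allclose(
            ours.explained_fraction, ref.proportion_explained[:3], atol=1e-8
        )

    def test_asymmetric_input_rejected(self):
        with pytest.raises(ValueError):
            DistanceMatrix(["a", "b"], np.array([[0.0, 0.2], [0.3, 0.0]]))


class TestPCA:
    def test_anticorrelated_blocks_rank_one(self):
        base = np.array([1, 1, 1, 0, 0, 0], dtype=np.int8)
        scores = np.column_stack([base] * 5 + [1 - base] * 5)
        res = pca(make_matrix(scores), 3)
        assert res.explained_fraction[0] > 0.999
        signs = np.sign(res.loadings[:, 0])
        assert len(set(signs[:5])) == 1 and signs[0] == -signs[5]

    def test_two_group_panel_separated_by_pc1(self, small_panel):
        res = pca(small_panel.matrix, 2)
        truth = np.array(
            [small_panel.truth_labels[g] for g in small_panel.matrix.genotype_ids]
        )
        side = (res.coordinates[:, 0] > 0).astype(int)
        assert max((side == truth).mean(), (side != truth).mean()) >= 0.95

    def test_explained_fractions_match_eigendecomposition(self, rng):
        mat = random_matrix(rng, 10, 20, missing_rate=0.0)
        res = pca(mat, 5)
        x = mat.scores.astype(float)
        xc = x - x.mean(axis=0)
        evals = np.sort(np.linalg.eigvalsh(np.cov(xc, rowvar=False)))[::-1]
        np.testing.assert_allclose(
            res.explained_fraction, (evals / evals.sum())[:5], atol=1e-9
        )
        assert res.explained_fraction.sum() <= 1.0 + 1e-12
        assert np.all(np.diff(res.explained_fraction) <= 1e-12)

    def test_constant_column_zero_loading(self):
        scores = np.array([[1, 1], [0, 1], [1, 1], [0, 1]], dtype=np.int8)
        res = pca(make_matrix(scores), 1)
        assert abs(res.loadings[1, 0]) < 1e-12


class TestTopLoadings:
    def test_count_rule(self, rng):
        mat = random_matrix(rng, 10, 100, missing_rate=0.0)
        res = pca(mat, 2)
        assert len(top_loading_markers(res, 0.05, 1)) == 5

    def test_block_markers_dominate_loadings(self, small_panel):
        res = pca(small_panel.matrix, 2)
        top = top_loading_markers(res, 0.05, 1)
        ent = small_panel.map.entries
        block = set(ent.loc[
            (ent["chromosome"] == "2D") & ent["position_cM"].between(10, 30),
            "marker_id",
        ])
        hits = len(block & set(top["marker_id"]))
        assert hits / len(block) >= 0.8

    def test_ranking_invariant_under_sign_flip(self, rng):
        mat = random_matrix(rng, 10, 40, missing_rate=0.0)
        res = pca(mat, 1)
        flipped = type(res)(
            method=res.method, ids=res.ids, coordinates=-res.coordinates,
            explained_fraction=res.explained_fraction, loadings=-res.loadings,
            marker_ids=res.marker_ids,
        )
        a = top_loading_markers(res, 0.2, 1)["marker_id"].tolist()
        b = top_loading_markers(flipped, 0.2, 1)["marker_id"].tolist()
        assert a == b

    def test_invalid_fraction_rejected(self, rng):
        res = pca(random_matrix(rng, 5, 10), 1)
        with pytest.raises(ValueError):
            top_loading_markers(res, 0.0)


class TestOutliers:
    def _result(self, coords):
        from dartpop.ordination import OrdinationResult
        return OrdinationResult(
            method="PCoA", ids=[f"g{i}" for i in range(len(coords))],
            coordinates=np.asarray(coords, float),
            explained_fraction=np.array([0.5, 0.3]),
        )

    def test_single_far_point_flagged(self, rng):
        cloud = rng.normal(size=(30, 2))
        spread = np.linalg.norm(cloud - cloud.mean(0), axis=1).std()
        coords = np.vstack([cloud, [20 * spread, 0]])
        assert flag_outliers(self._result(coords)) == ["g30"]

    def test_flags_invariant_under_axis_sign_flip(self, rng):
        coords = rng.normal(size=(40, 2))
        coords[0] *= 15
        res = self._result(coords)
        res_flipped = self._result(coords * np.array([-1.0, 1.0]))
        assert flag_outliers(res) == flag_outliers(res_flipped)

    def test_compact_minority_cluster_not_flagged(self, rng):
        # a well-separated 26/66 two-group layout is structure, not outliers
        minority = rng.normal(size=(26, 2)) * 0.5 + [10.0, 0.0]
        majority = rng.normal(size=(66, 2)) * 0.5
        assert flag_outliers(self._result(np.vstack([minority, majority]))) == []

    def test_homogeneous_cloud_rarely_flagged(self):
        # null calibration: n=92 Gaussian cloud, k_sd=4 -> zero flags >= 95/100
        clean = 0
        for seed in range(100):
            coords = np.random.default_rng(seed).normal(size=(92, 2))
            if not flag_outliers(self._result(coords)):
                clean += 1
        assert clean >= 95


class TestAssociation:
    def test_perfectly_confounded_band(self):
        scores = np.array([[1]] * 26 + [[0]] * 66, dtype=np.int8)
        labels = {f"g{i}": (0 if i < 26 else 1) for i in range(92)}
        out = marker_group_association(make_matrix(scores), labels)
        assert out["p_value"].iloc[0] < 1e-15

    def test_chi2_and_fisher_branches_agree_on_moderate_table(self):
        # 20/6 carriers vs 10/56 non-carriers
        scores = np.array([[1]] * 20 + [[0]] * 6 + [[1]] * 10 + [[0]] * 56, dtype=np.int8)
        labels = {f"g{i}": (0 if i < 26 else 1) for i in range(92)}
        mat = make_matrix(scores)
        out = marker_group_association(mat, labels)
        from scipy import stats as sps
        table = [[20, 10], [6, 56]]
        p_f = sps.fisher_exact(table).pvalue
        p_c = sps.chi2_contingency(table, correction=True).pvalue
        assert out["p_value"].iloc[0] in (p_f, p_c)
        assert 0.1 < np.log10(p_f) / np.log10(p_c) < 10

    def test_three_groups_rejected(self, rng):
        mat = random_matrix(rng, 9, 5)
        labels = {g: i % 3 for i, g in enumerate(mat.genotype_ids)}
        with pytest.raises(ValueError, match="one-vs-rest"):
            marker_group_association(mat, labels)

    def test_null_type_one_error_controlled(self):
        # balanced band frequencies in both groups; alpha 0.05
        rng = np.random.default_rng(99)
        n_markers, n = 2000, 92
        scores = (rng.random((n, n_markers)) < 0.5).astype(np.int8)
        labels = {f"g{i}": (0 if i < 46 else 1) for i in range(n)}
        out = marker_group_association(make_matrix(scores), labels)
        assert (out["p_value"] < 0.05).mean() <= 0.06
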