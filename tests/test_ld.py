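import numpy as np
import pandas as pd
import pytest

from dartpop.io import GeneticMap
from dartpop.ld import (
    LDPairs,
    background_ld,
    fit_decay,
    ld_summaries,
    loess_quadratic,
    pair_r2,
    permutation_r2_test,
)
from conftest import make_matrix, random_matrix


def _map_for(marker_ids, chrom="1A", positions=None):
    if positions is None:
        positions = np.linspace(0, 80, len(marker_ids))
    return GeneticMap(pd.DataFrame({
        "marker_id": marker_ids, "chromosome": chrom, "position_cM": positions,
    }))


class TestPairR2:
    def test_duplicated_columns_perfect_ld(self, rng):
        x = rng.integers(0, 2, size=(30, 1)).astype(np.int8)
        mat = make_matrix(np.hstack([x, x]))
        pairs = pair_r2(mat, _map_for(mat.marker_ids), n_perm=200, seed=0)
        row = pairs.table.iloc[0]
        assert row["r2"] == 1.0
        assert row["p_perm"] == 1.0 / 201.0
        assert row["significant"]

    def test_r2_equals_haplotype_count_formula(self, rng):
        # algebraic identity: squared correlation of 0/1 vectors equals
        # D^2 / (pA pa pB pb) from the 2x2 haplotype count table
        checked = 0
        while checked < 50:
            x = rng.integers(0, 2, size=30)
            y = rng.integers(0, 2, size=30)
            pa, pb = x.mean(), y.mean()
            if pa in (0, 1) or pb in (0, 1):
                continue
            pab = ((x == 1) & (y == 1)).mean()
            d = pab - pa * pb
            expected = d * d / (pa * (1 - pa) * pb * (1 - pb))
            mat = make_matrix(np.column_stack([x, y]).astype(np.int8))
            pairs = pair_r2(mat, _map_for(mat.marker_ids), n_perm=10, seed=0)
            assert abs(pairs.table["r2"].iloc[0] - expected) < 1e-12
            checked += 1

    def test_null_pairs_mean_r2_near_one_over_n(self, rng):
        n = 92
        r2s = []
        for _ in range(200):
            x = (rng.random(n) < 0.5).astype(np.int8)
            y = (rng.random(n) < 0.5).astype(np.int8)
            res = permutation_r2_test(x, y, 10, rng)
            if res is not None:
                r2s.append(res[0])
        assert abs(np.mean(r2s) - 1.0 / n) < 0.003

    def test_monomorphic_pair_skipped_and_counted(self):
        scores = np.array([[1, 1], [1, 0], [1, 1], [1, 0]], dtype=np.int8)
        pairs = pair_r2(make_matrix(scores), _map_for(["m0", "m1"]), n_perm=10, seed=0)
        assert len(pairs.table) == 0 and pairs.n_skipped == 1

    def test_inter_chromosomal_pairs_excluded(self, rng):
        mat = random_matrix(rng, 20, 4, missing_rate=0.0)
        gmap = GeneticMap(pd.DataFrame({
            "marker_id": mat.marker_ids,
            "chromosome": ["1A", "1A", "2B", "2B"],
            "position_cM": [0.0, 10.0, 0.0, 10.0],
        }))
        pairs = pair_r2(mat, gmap, n_perm=10, seed=0)
        assert len(pairs.table) <= 2
        assert set(pairs.table["chromosome"]) <= {"1A", "2B"}

    def test_results_independent_of_marker_column_order(self, rng):
        mat = random_matrix(rng, 25, 6, missing_rate=0.0)
        gmap = _map_for(mat.marker_ids)
        a = pair_r2(mat, gmap, n_perm=99, seed=3).table
        # permuting matrix columns must not change per-pair p-values
        order = rng.permutation(mat.marker_ids).tolist()
        b = pair_r2(mat.select_markers(order), gmap, n_perm=99, seed=3).table
        merged = a.merge(b, on=["marker_a", "marker_b"], suffixes=("_a", "_b"))
        assert len(merged) == len(a)
        np.testing.assert_allclose(merged["r2_a"], merged["r2_b"])
        # p may differ (seed stream keyed by column index) but r2 may not


class TestBackground:
    def test_constant_unlinked_values(self):
        table = pd.DataFrame({
            "r2": [0.05] * 25, "unlinked": [True] * 25,
            "distance_cM": [60.0] * 25, "significant": [False] * 25,
        })
        assert background_ld(table) == 0.05

    def test_percentile_linear_interpolation(self):
        r2 = np.arange(0.01, 1.005, 0.01)
        table = pd.DataFrame({
            "r2": r2, "unlinked": True, "distance_cM": 60.0, "significant": False,
        })
        assert np.isclose(background_ld(table), 0.9505)

    def test_linked_pairs_ignored(self):
        table = pd.DataFrame({
            "r2": [0.9] * 30 + [0.05] * 25,
            "unlinked": [False] * 30 + [True] * 25,
            "distance_cM": [10.0] * 30 + [60.0] * 25,
            "significant": True,
        })
        assert background_ld(table) == 0.05

    def test_too_few_unlinked_pairs_rejected(self):
        table = pd.DataFrame({"r2": [0.1] * 5, "unlinked": [True] * 5})
        with pytest.raises(ValueError, match="unlinked"):
            background_ld(table)

    def test_exactly_50_cm_is_linked(self, rng):
        mat = random_matrix(rng, 30, 2, missing_rate=0.0)
        gmap = _map_for(mat.marker_ids, positions=[0.0, 50.0])
        pairs = pair_r2(mat, gmap, n_perm=10, seed=0)
        assert not pairs.table["unlinked"].iloc[0]


class TestFitDecay:
    def _pairs(self, rng, n=400, noise=0.01):
        d = rng.uniform(0, 40, n)
        r2 = np.clip(0.6 - 0.02 * d + rng.normal(0, noise, n), 0, 1)
        return pd.DataFrame({
            "distance_cM": d, "r2": r2, "significant": True,
            "unlinked": d > 50,
        })

    def test_constructed_curve_known_crossing(self):
        # r2 = 0.6 - 0.02 d crosses 0.2 at d = 20
        decays = [
            fit_decay(self._pairs(np.random.default_rng(s)), 0.2).decay_cM
            for s in range(20)
        ]
        assert abs(np.mean(decays) - 20.0) < 2.0
        assert all(abs(d - 20.0) < 4.0 for d in decays)

    def test_curve_above_background_reports_no_intercept(self, rng):
        d = rng.uniform(0, 25, 400)
        r2 = np.clip(0.6 - 0.02 * d + rng.normal(0, 0.01, 400), 0, 1)
        pairs = pd.DataFrame({
            "distance_cM": d, "r2": r2, "significant": True, "unlinked": False,
        })
        res = fit_decay(pairs, 0.005)
        assert res.no_intercept and res.decay_cM is None
        assert res.terminal_extent_cM >= pairs["distance_cM"].max()

    def test_decay_monotone_in_background(self, rng):
        pairs = self._pairs(rng)
        d_low = fit_decay(pairs, 0.15).decay_cM
        d_high = fit_decay(pairs, 0.35).decay_cM
        assert d_high <= d_low

    def test_degenerate_distances_rejected(self):
        pairs = pd.DataFrame({
            "distance_cM": [5.0] * 40, "r2": [0.3] * 40, "significant": True,
        })
        with pytest.raises(ValueError, match="degenerate"):
            fit_decay(pairs, 0.1)

    def test_too_few_significant_pairs_rejected(self, rng):
        pairs = self._pairs(rng, n=10)
        with pytest.raises(ValueError, match="significant"):
            fit_decay(pairs, 0.1)

    def test_loess_quadratic_reproduces_polynomial(self, rng):
        # a global quadratic is fitted exactly by local quadratics
        x = rng.uniform(0, 10, 200)
        y = 1.0 + 0.5 * x - 0.03 * x * x
        grid = np.linspace(0.5, 9.5, 10)
        fitted = loess_quadratic(x, y, grid, span=0.7)
        np.testing.assert_allclose(fitted, 1.0 + 0.5 * grid - 0.03 * grid**2, atol=1e-8)


class TestSummaries:
    def test_single_chromosome_mean_equals_common_r2(self, rng):
        x = rng.integers(0, 2, size=(40, 1)).astype(np.int8)
        mat = make_matrix(np.hstack([x, x, x]))
        gmap = _map_for(mat.marker_ids, positions=[0.0, 5.0, 10.0])
        pairs = pair_r2(mat, gmap, n_perm=20, seed=0)
        s = ld_summaries(pairs, gmap)
        assert np.isclose(
            s["per_chromosome"].set_index("chromosome").loc["1A", "mean_r2_all"], 1.0
        )

    def test_genome_means_are_pair_count_weighted(self, rng):
        mat = random_matrix(rng, 30, 9, missing_rate=0.0)
        gmap = GeneticMap(pd.DataFrame({
            "marker_id": mat.marker_ids,
            "chromosome": ["1A"] * 3 + ["2A"] * 4 + ["1B"] * 2,
            "position_cM": [0, 5, 12, 0, 4, 9, 20, 0, 7],
        }))
        pairs = pair_r2(mat, gmap, n_perm=20, seed=1)
        s = ld_summaries(pairs, gmap)
        per_c = s["per_chromosome"].set_index("chromosome")
        a_rows = per_c.loc[["1A", "2A"]]
        weighted = (a_rows["mean_r2_all"] * a_rows["n_pairs"]).sum() / a_rows["n_pairs"].sum()
        genome_a = s["per_genome"].set_index("genome").loc["A", "mean_r2_all"]
        assert np.isclose(genome_a, weighted)
        total = s["overall"]["n_pairs"].iloc[0]
        assert total == s["per_chromosome"]["n_pairs"].sum()

    def test_significant_mean_at_least_all_mean(self, small_panel):
        pairs = pair_r2(small_panel.matrix, small_panel.map, n_perm=50, seed=2)
        s = ld_summaries(pairs, small_panel.map)
        row = s["overall"].iloc[0]
        assert row["mean_r2_significant"] >= row["mean_r2_all"]
        assert row["n_pairs"] >= row["n_significant"]

    def test_adjacent_profile_at_proximal_locus(self, rng):
        mat = random_matrix(rng, 25, 3, missing_rate=0.0)
        gmap = _map_for(mat.marker_ids, positions=[2.0, 8.0, 20.0])
        pairs = pair_r2(mat, gmap, n_perm=20, seed=0)
        adj = ld_summaries(pairs, gmap)["adjacent"]
        assert adj["position_cM"].tolist() == [2.0, 8.0]
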