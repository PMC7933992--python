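import numpy as np
import pandas as pd
import pytest

from tmgate.errors import InputError
from tmgate.markers import (
    ConsensusParams,
    SimilarityParams,
    auc_grid,
    auc_similarity,
    bh_adjust,
    consensus_rank,
    grid_thresholds,
    marker_scan,
    overlap_test,
)


def rank_auc(pos, neg):
    """Exact rank-based AUC oracle: (concordant + 0.5 * ties) / (n1 * n0)."""
    pos, neg = np.asarray(pos), np.asarray(neg)
    gt = (pos[:, None] > neg[None, :]).sum()
    eq = (pos[:, None] == neg[None, :]).sum()
    return (gt + 0.5 * eq) / (len(pos) * len(neg))


class TestAucGrid:
    def test_thirty_nine_thresholds(self):
        rng = np.random.default_rng(0)
        expr = rng.gamma(1.0, 2.0, 500)
        assert len(grid_thresholds(expr)) == 39

    def test_perfect_separation_auc_one(self):
        expr = np.array([5.0, 4.0, 3.0, 0.0, 1.0, 2.0])
        labels = np.array([1, 1, 1, 0, 0, 0], bool)
        grid = auc_grid(expr, labels)
        assert grid.auc == pytest.approx(1.0, abs=1e-12)

    def test_grid_close_to_rank_auc_small_example(self):
        expr = np.array([3.0, 1.0, 2.0, 0.0])
        labels = np.array([1, 1, 0, 0], bool)
        grid = auc_grid(expr, labels)
        assert abs(grid.auc - 0.75) <= 0.02

    @pytest.mark.parametrize("seed", range(5))
    def test_grid_close_to_rank_auc_random_genes(self, seed):
        rng = np.random.default_rng(seed)
        n = 300
        labels = np.zeros(n, bool)
        labels[:60] = True
        expr = rng.negative_binomial(2, 0.4, n).astype(float) + 0.8 * labels * rng.random(n)
        grid = auc_grid(expr, labels)
        oracle = rank_auc(expr[labels], expr[~labels])
        assert abs(grid.auc - oracle) <= 0.02

    def test_directions_sum_to_one_for_tie_free_data(self):
        rng = np.random.default_rng(3)
        n = 200
        labels = np.zeros(n, bool)
        labels[:50] = True
        expr = rng.normal(labels * 0.7, 1.0)
        a_pos = auc_grid(expr, labels, direction="positive").auc
        a_neg = auc_grid(expr, labels, direction="negation").auc
        assert a_pos + a_neg == pytest.approx(1.0, abs=0.02)

    def test_constant_gene_degenerates_to_half(self):
        expr = np.full(50, 2.0)
        labels = np.zeros(50, bool)
        labels[:10] = True
        assert auc_grid(expr, labels).auc == pytest.approx(0.5)

    def test_single_class_rejected(self):
        with pytest.raises(InputError):
            auc_grid(np.arange(5.0), np.ones(5, bool))


class TestBhAdjust:
    def test_hand_computed_example(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_single_p_unchanged(self):
        assert bh_adjust([0.2])[0] == pytest.approx(0.2)

    def test_all_ones_stay_one(self):
        np.testing.assert_allclose(bh_adjust([1.0, 1.0, 1.0]), 1.0)

    def test_order_invariance(self):
        rng = np.random.default_rng(4)
        p = rng.random(30)
        perm = rng.permutation(30)
        np.testing.assert_allclose(bh_adjust(p)[perm], bh_adjust(p[perm]))

    def test_out_of_range_rejected(self):
        with pytest.raises(InputError):
            bh_adjust([0.5, 1.5])


class TestConsensusRank:
    def _tables(self, support, aucs):
        """6 samples; marker significant (q=0.01) in `support` of them."""
        out = {}
        for s in range(6):
            rows = []
            for gene in support:
                rows.append({
                    "gene": gene, "direction": "marker",
                    "q": 0.01 if s < support[gene] else 0.5,
                    "auc": aucs[gene],
                })
            out[f"S{s}"] = pd.DataFrame(rows)
        return out

    def test_support_threshold(self):
        tables = self._tables({"A": 5, "B": 4, "C": 3}, {"A": 0.7, "B": 0.77, "C": 0.9})
        ranked = consensus_rank(tables, ConsensusParams(min_samples=4))
        assert set(ranked["gene"]) == {"A", "B"}

    def test_ranked_by_mean_auc_descending(self):
        tables = self._tables({"A": 5, "B": 5}, {"A": 0.70, "B": 0.77})
        ranked = consensus_rank(tables, ConsensusParams(min_samples=4))
        assert list(ranked["gene"]) == ["B", "A"]

    def test_exclusion_list_overrides_support(self):
        tables = self._tables({"CD8A": 6, "B": 5}, {"CD8A": 0.9, "B": 0.7})
        ranked = consensus_rank(tables, ConsensusParams(min_samples=4))
        assert "CD8A" not in set(ranked["gene"])


class TestOverlapTest:
    def test_full_overlap_combinatorial_value(self):
        genes = [f"g{i}" for i in range(5)]
        k, p = overlap_test(genes, genes, universe=10)
        assert k == 5
        assert p == pytest.approx(1 / 252, rel=1e-9)

    def test_zero_overlap_in_large_universe(self):
        _, p = overlap_test(["a"], ["b"], universe=1000)
        assert p == pytest.approx(1.0, abs=2e-3)

    def test_set_equal_to_universe_forces_p_one(self):
        a = [f"g{i}" for i in range(10)]
        _, p = overlap_test(a, a[:4], universe=10)
        assert p == pytest.approx(1.0)


class TestAucSimilarity:
    def _tables(self, n_samples=4, n_genes=50, seed=0, identical=False):
        rng = np.random.default_rng(seed)
        genes = [f"g{i}" for i in range(n_genes)]
        base = rng.random(n_genes)
        out = {}
        for s in range(n_samples):
            vals = base if identical else rng.random(n_genes)
            out[f"S{s}"] = pd.Series(vals, index=genes)
        patient = {f"S{s}": f"P{s // 2}" for s in range(n_samples)}
        return out, patient

    def test_identical_profiles_give_r_one_in_both_strata(self):
        tables, patient = self._tables(identical=True)
        res = auc_similarity(tables, patient)
        assert set(res["stratum"]) == {"within-patient", "between-patient"}
        assert np.allclose(res["pearson_r"], 1.0)

    def test_independent_profiles_give_small_r(self):
        tables, patient = self._tables(n_genes=200, seed=1)
        res = auc_similarity(tables, patient)
        assert np.all(np.abs(res["pearson_r"]) < 0.2)

    def test_fixed_seed_is_deterministic(self):
        tables, patient = self._tables(seed=2)
        r1 = auc_similarity(tables, patient, SimilarityParams(rng_seed=27))
        r2 = auc_similarity(tables, patient, SimilarityParams(rng_seed=27))
        pd.testing.assert_frame_equal(r1, r2)

    def test_too_few_shared_genes_rejected(self):
        tables = {"S0": pd.Series([0.5], index=["g0"]),
                  "S1": pd.Series([0.5], index=["g0"])}
        with pytest.raises(InputError):
            auc_similarity(tables, {"S0": "P0", "S1": "P1"})


class TestMarkerScan:
    def test_scan_recovers_planted_negation_marker(self, sim_sample):
        bundle = sim_sample.bundle
        comp = bundle.cell_meta["compartment"] == "blood"
        sub = bundle.subset_cells(comp.to_numpy())
        tm = sim_sample.truth.tm_blood.to_numpy()
        table = marker_scan(sub.counts, list(sub.gene_ids), tm)
        top = table.sort_values("q").iloc[0]
        assert top["gene"].startswith("MARK")
        assert top["direction"] == "marker_negation"
        assert top["q"] < 0.05
        # q is never below p within the sample's gene family
        assert (table["q"] >= table["p"] - 1e-12).all()
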