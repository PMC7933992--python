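import numpy as np
import pandas as pd
import pytest

from tmgate.errors import InputError
from tmgate import tcr
from tmgate.tcr import (
    assign_clonotypes,
    clone_size_table,
    consensus_cluster_matching,
    expansion_correlation,
    label_matching,
    pseudobulk_by_clone,
    read_contigs,
)

from conftest import make_bundle


def chains_df(records):
    """records: (barcode, chain, cdr3[, productive])"""
    rows = [(r[0], r[1], r[2], r[3] if len(r) > 3 else True) for r in records]
    return pd.DataFrame(rows, columns=["barcode", "chain", "cdr3", "productive"])


class TestAssignClonotypes:
    def test_identical_chain_sets_share_a_clone(self):
        df = chains_df([("A", "TRA", "CAF"), ("A", "TRB", "CBF"),
                        ("B", "TRA", "CAF"), ("B", "TRB", "CBF")])
        m = assign_clonotypes(df)
        assert m["A"] == m["B"] is not None

    def test_extra_chain_makes_a_different_clone(self):
        # all detected chains must be shared, not just a common pair
        df = chains_df([("A", "TRA", "CAF"), ("A", "TRB", "CBF"),
                        ("C", "TRA", "CAF"), ("C", "TRA", "CA2F"), ("C", "TRB", "CBF")])
        m = assign_clonotypes(df)
        assert m["A"] is not None and m["C"] is not None
        assert m["A"] != m["C"]

    def test_single_chain_cell_excluded(self):
        df = chains_df([("D", "TRA", "CAF")])
        assert assign_clonotypes(df)["D"] is None

    def test_nonproductive_chains_ignored_by_default(self):
        df = chains_df([("A", "TRA", "CAF"), ("A", "TRB", "CBF"),
                        ("B", "TRA", "CAF"), ("B", "TRB", "CBF"),
                        ("B", "TRB", "CXF", False)])
        m = assign_clonotypes(df)
        assert m["A"] == m["B"]
        m2 = assign_clonotypes(df, include_nonproductive=True)
        assert m2["A"] != m2["B"]

    def test_duplicate_chain_counts_once(self):
        df = chains_df([("A", "TRA", "CAF"), ("A", "TRA", "CAF"), ("A", "TRB", "CBF"),
                        ("B", "TRA", "CAF"), ("B", "TRB", "CBF")])
        m = assign_clonotypes(df)
        assert m["A"] == m["B"]

    def test_record_order_invariance(self):
        recs = [("A", "TRA", "CAF"), ("A", "TRB", "CBF"), ("B", "TRA", "CGF"),
                ("B", "TRB", "CHF"), ("C", "TRA", "CAF"), ("C", "TRB", "CBF")]
        m1 = assign_clonotypes(chains_df(recs))
        m2 = assign_clonotypes(chains_df(recs[::-1]))
        assert m1 == m2

    def test_malformed_chain_rejected(self):
        df = chains_df([("A", "IGH", "CAF")])
        with pytest.raises(InputError, match="IGH"):
            assign_clonotypes(df)

    def test_empty_table_returns_empty_map(self):
        assert assign_clonotypes(chains_df([])) == {}


def _toy_compartments():
    k1 = (("TRA", "C1F"), ("TRB", "C2F"))
    k2 = (("TRA", "C3F"), ("TRB", "C4F"))
    k3 = (("TRA", "C5F"), ("TRB", "C6F"))
    blood = {f"b{i}": k1 for i in range(3)} | {"b3": k2}
    tumor = {f"t{i}": k2 for i in range(5)} | {"t5": k3, "t6": k3}
    return blood, tumor


class TestLabelMatching:
    def test_toy_counts(self):
        # blood = {k1: 3, k2: 1}, tumor = {k2: 5, k3: 2} -> 1 TM cell, 5 blood-matching
        blood, tumor = _toy_compartments()
        lab = label_matching(blood, tumor)
        assert (lab["label"] == tcr.TM).sum() == 1
        assert (lab["label"] == tcr.BLOOD_MATCHING).sum() == 5

    def test_disjoint_clone_sets_give_zero_tm(self):
        blood = {"b0": (("TRA", "CAF"), ("TRB", "CBF"))}
        tumor = {"t0": (("TRA", "CXF"), ("TRB", "CYF"))}
        lab = label_matching(blood, tumor)
        assert (lab["label"] == tcr.TM).sum() == 0

    def test_symmetry_of_distinct_matched_keys(self, sim_sample):
        clones = assign_clonotypes(sim_sample.chains)
        comp = sim_sample.bundle.cell_meta["compartment"]
        blood = {bc: clones.get(bc) for bc in comp.index[comp == "blood"]}
        tumor = {bc: clones.get(bc) for bc in comp.index[comp == "tumor"]}
        lab = label_matching(blood, tumor)
        tm_keys = set(lab.loc[lab["label"] == tcr.TM, "clone_key"])
        bm_keys = set(lab.loc[lab["label"] == tcr.BLOOD_MATCHING, "clone_key"])
        assert tm_keys == bm_keys

    def test_excluded_cells_labeled(self):
        blood = {"b0": None}
        tumor = {"t0": (("TRA", "CXF"), ("TRB", "CYF"))}
        lab = label_matching(blood, tumor)
        assert lab.loc["b0", "label"] == tcr.EXCLUDED


class TestConsensusMatching:
    def test_agreement_and_conflict(self):
        idx = ["a", "b", "c", "d"]
        algo1 = pd.Series([True, False, True, False], index=idx)
        algo2 = pd.Series([True, False, False, True], index=idx)
        labels, counts = consensus_cluster_matching(algo1, algo2)
        assert labels["a"] == tcr.TM and labels["b"] == tcr.NON_TM
        assert labels["c"] == labels["d"] == tcr.CONFLICTED
        assert counts == {"TM": 1, "non-TM": 1, "conflicted": 2}

    def test_all_agreeing_has_no_conflicts(self):
        idx = list("abc")
        s = pd.Series([True, True, False], index=idx)
        _, counts = consensus_cluster_matching(s, s.copy())
        assert counts["conflicted"] == 0

    def test_mismatched_cell_sets_rejected(self):
        with pytest.raises(InputError):
            consensus_cluster_matching(pd.Series([True], index=["a"]),
                                       pd.Series([True], index=["b"]))


class TestCloneSizes:
    def test_expansion_values(self):
        k1 = (("TRA", "C1F"), ("TRB", "C2F"))
        k2 = (("TRA", "C3F"), ("TRB", "C4F"))
        cells = {"a": k1, "b": k1, "c": k1, "d": k2}
        sizes, expansion = clone_size_table(cells, "blood")
        assert sorted(expansion.values) == [1, 3, 3, 3]
        assert sizes["size"].sum() == 4  # sizes sum to clonotyped cell count

    def test_too_few_shared_clones_rejected(self):
        k1, k2 = ("k1",), ("k2",)
        with pytest.raises(InputError):
            expansion_correlation({k1: 4, k2: 1}, {k1: 8, k2: 2})

    def test_spearman_toy(self):
        sizes_b = {("k1",): 4, ("k2",): 1, ("k3",): 2}
        sizes_t = {("k1",): 8, ("k2",): 2, ("k3",): 3}
        rho, _ = expansion_correlation(sizes_b, sizes_t)
        assert rho == pytest.approx(1.0)


class TestPseudobulk:
    def test_counts_sum_within_clone(self):
        k1 = (("TRA", "C1F"), ("TRB", "C2F"))
        b = make_bundle([[1, 2], [0, 5]], barcodes=["a", "b"])
        df = pseudobulk_by_clone(b, {"a": k1, "b": k1}, ["a", "b"], cpm_min=0.0)
        np.testing.assert_array_equal(df.to_numpy(), [[3, 5]])

    def test_single_cell_clone_is_identity(self):
        k1 = (("TRA", "C1F"), ("TRB", "C2F"))
        b = make_bundle([[7], [3]], barcodes=["a"])
        df = pseudobulk_by_clone(b, {"a": k1}, ["a"], cpm_min=0.0)
        np.testing.assert_array_equal(df.to_numpy(), [[7, 3]])

    def test_cpm_filter_drops_low_aggregate_genes(self):
        # 3 clones; gene g2 has 1 count of 2,000,001 total -> < 1 CPM, dropped
        k = [((f"a{i}",),) for i in range(3)]
        counts = np.array([[1_000_000, 600_000, 400_000],
                           [0, 0, 1],
                           [0, 1, 0]])
        b = make_bundle(counts, barcodes=["a", "b", "c"])
        cells = {"a": k[0], "b": k[1], "c": k[2]}
        df = pseudobulk_by_clone(b, cells, ["a", "b", "c"], cpm_min=1.0)
        # total = 2,000,002; g1 and g2 each have 1 count = 0.49999 CPM -> dropped
        assert list(df.columns) == ["g0"]

    def test_empty_class_warns_and_returns_empty(self):
        b = make_bundle([[1]], barcodes=["a"])
        df = pseudobulk_by_clone(b, {"a": None}, ["a"])
        assert len(df) == 0


class TestSimulatedRecovery:
    def test_planted_tm_fraction_recovered(self, sim_sample):
        clones = assign_clonotypes(sim_sample.chains)
        comp = sim_sample.bundle.cell_meta["compartment"]
        blood = {bc: clones.get(bc) for bc in comp.index[comp == "blood"]}
        tumor = {bc: clones.get(bc) for bc in comp.index[comp == "tumor"]}
        lab = label_matching(blood, tumor)
        paired = lab[(lab["compartment"] == "blood")
                     & lab["label"].isin([tcr.TM, tcr.NON_TM])]
        f = sim_sample.config.shared_clone_fraction
        frac = (paired["label"] == tcr.TM).mean()
        sd = np.sqrt(f * (1 - f) / len(paired))
        assert abs(frac - f) <= 3 * sd

    def test_contig_dialect_round_trip(self, tmp_path, sim_small):
        path = tmp_path / "contigs.csv"
        sim_small.chains.to_csv(path, index=False)
        df = read_contigs(path)
        assert {"barcode", "chain", "cdr3", "productive"} <= set(df.columns)
        assert df["productive"].dtype == bool
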