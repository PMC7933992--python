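import itertools

import numpy as np
import pandas as pd
import pytest

from tmgate.errors import InputError
from tmgate.gates import (
    GateEvalParams,
    GateEvaluation,
    Literal,
    enumerate_gates,
    evaluate_gate,
    parse_gate,
    pareto_filter,
    penalty,
    select_best_gate,
)


def count_monotone_nonconstant(k):
    """Independent oracle: count nonconstant monotone boolean functions on k vars."""
    n_rows = 2 ** k
    count = 0
    for bits in range(1, 2 ** n_rows - 1):  # skip constants
        table = [(bits >> r) & 1 for r in range(n_rows)]
        ok = True
        for r in range(n_rows):
            for i in range(k):
                if not (r >> i) & 1:
                    if table[r] > table[r | (1 << i)]:
                        ok = False
                        break
            if not ok:
                break
        count += ok
    return count


class TestParse:
    def test_paper_style_gate_structure(self):
        g = parse_gate("CCR7^low & (FLT3LG^low | LTB^low)")
        assert g.op == "and"
        assert g.left.op == "lit" and str(g.left.literal) == "CCR7^low"
        assert g.right.op == "or"
        assert str(g) == "CCR7^low & (FLT3LG^low | LTB^low)"

    def test_single_literal(self):
        g = parse_gate("A^high")
        assert g.op == "lit" and g.literal == Literal("A", "high")

    def test_precedence_and_binds_tighter(self):
        g = parse_gate("A^low | B^low & C^low")
        assert g.op == "or"
        assert g.right.op == "and"

    def test_round_trip_canonical_string(self):
        for text in ["A^low", "A^low & B^high", "(A^low | B^low) & C^high"]:
            assert str(parse_gate(str(parse_gate(text)))) == str(parse_gate(text))

    @pytest.mark.parametrize("bad", ["A^low &", "A^mid", "(A^low", "& B^low", ""])
    def test_syntax_errors(self, bad):
        with pytest.raises(InputError):
            parse_gate(bad)


class TestEnumerate:
    @pytest.mark.parametrize("k,expected", [(1, 1), (2, 4), (3, 18), (4, 166)])
    def test_counts_match_monotone_function_oracle(self, k, expected):
        lits = [Literal(f"M{i}", "low") for i in range(k)]
        gates = enumerate_gates(lits)
        assert len(gates) == expected
        if k <= 3:  # the full 2^(2^4) oracle sweep is done once, below
            assert expected == count_monotone_nonconstant(k)

    def test_four_literal_count_matches_oracle(self):
        assert count_monotone_nonconstant(4) == 166

    def test_truth_tables_are_distinct(self):
        lits = [Literal(f"M{i}", "low") for i in range(4)]
        gates = enumerate_gates(lits)
        tables = {g.truth_table(lits) for g in gates}
        assert len(tables) == len(gates)

    def test_two_literal_gates_are_the_expected_four(self):
        lits = [Literal("A", "low"), Literal("B", "low")]
        names = {str(g) for g in enumerate_gates(lits)}
        assert names == {"A^low", "B^low", "A^low & B^low", "A^low | B^low"}

    def test_conflicting_directions_rejected(self):
        with pytest.raises(InputError):
            enumerate_gates([Literal("A", "low"), Literal("A", "high")])

    def test_more_than_four_literals_rejected(self):
        with pytest.raises(InputError):
            enumerate_gates([Literal(f"M{i}", "low") for i in range(5)])


class TestEvaluate:
    def _toy(self):
        # 3 TM, 3 non-TM cells; gene X low in TM, gene Y noisy
        expr = pd.DataFrame({
            "X": [0, 0, 2, 3, 0, 4],
            "Y": [1, 0, 0, 0, 2, 2],
        }, dtype=float)
        labels = np.array([1, 1, 1, 0, 0, 0], bool)
        return expr, labels

    def test_hand_counted_confusion_matrix(self):
        expr, labels = self._toy()
        ev = evaluate_gate(parse_gate("X^low"), expr, labels)
        # X < 0.001 for cells 0,1,4 -> TP=2, FN=1, FP=1, TN=2
        assert (ev.tp, ev.fn, ev.fp, ev.tn) == (2, 1, 1, 2)
        assert ev.sensitivity == pytest.approx(2 / 3)
        assert ev.specificity == pytest.approx(2 / 3)

    def test_always_true_gate(self):
        expr, labels = self._toy()
        ev = evaluate_gate(parse_gate("X^low | X^high"), expr, labels)
        # X^low | X^high passes unless X == threshold exactly; all counts differ
        assert ev.sensitivity == 1.0 and ev.specificity == 0.0

    def test_zero_count_passes_low_literal_at_universal_threshold(self):
        expr = pd.DataFrame({"X": [0.0, 1.0]})
        labels = np.array([1, 0], bool)
        ev = evaluate_gate(parse_gate("X^low"), expr, labels,
                           GateEvalParams(universal_threshold=0.001))
        assert ev.tp == 1 and ev.fp == 0

    def test_missing_marker_raises_keyerror(self):
        expr, labels = self._toy()
        with pytest.raises(KeyError):
            evaluate_gate(parse_gate("Z^low"), expr, labels)

    def test_cell_order_invariance(self):
        expr, labels = self._toy()
        g = parse_gate("X^low & Y^low")
        ev1 = evaluate_gate(g, expr, labels)
        perm = np.random.default_rng(0).permutation(len(labels))
        ev2 = evaluate_gate(g, expr.iloc[perm].reset_index(drop=True), labels[perm])
        assert (ev1.sensitivity, ev1.specificity) == (ev2.sensitivity, ev2.specificity)

    def test_or_literal_never_decreases_sensitivity(self):
        rng = np.random.default_rng(5)
        expr = pd.DataFrame(rng.integers(0, 4, size=(200, 3)).astype(float),
                            columns=["A", "B", "C"])
        labels = rng.random(200) < 0.3
        base = evaluate_gate(parse_gate("A^low"), expr, labels)
        with_or = evaluate_gate(parse_gate("A^low | B^low"), expr, labels)
        with_and = evaluate_gate(parse_gate("A^low & C^low"), expr, labels)
        assert with_or.sensitivity >= base.sensitivity
        assert with_and.specificity >= base.specificity


def _random_evals(n, seed):
    rng = np.random.default_rng(seed)
    evals = []
    for i in range(n):
        s, c = rng.random(), rng.random()
        evals.append(GateEvaluation(parse_gate(f"M{i}^low"), s, c, penalty(s, c),
                                    0, 0, 0, 0))
    return evals


class TestParetoAndSelection:
    def test_toy_frontier(self):
        pts = [(0.9, 0.5), (0.8, 0.7), (0.7, 0.6)]
        evals = [GateEvaluation(parse_gate(f"M{i}^low"), s, c, penalty(s, c), 0, 0, 0, 0)
                 for i, (s, c) in enumerate(pts)]
        flags = pareto_filter(evals)
        assert flags == [True, True, False]

    def test_single_gate_is_pareto(self):
        evals = _random_evals(1, 0)
        assert pareto_filter(evals) == [True]

    def test_frontier_matches_quadratic_oracle(self):
        evals = _random_evals(166, 1)
        flags = pareto_filter(evals)
        for i, e in enumerate(evals):
            dominated = any(
                (o.sensitivity >= e.sensitivity and o.specificity >= e.specificity
                 and (o.sensitivity > e.sensitivity or o.specificity > e.specificity))
                for j, o in enumerate(evals) if j != i
            )
            assert flags[i] == (not dominated)

    def test_frontier_is_a_staircase(self):
        evals = _random_evals(166, 2)
        pareto_filter(evals)
        front = sorted([e for e in evals if e.pareto], key=lambda e: e.sensitivity)
        specs = [e.specificity for e in front]
        assert all(a > b for a, b in zip(specs, specs[1:]))

    def test_penalty_formula_values(self):
        assert penalty(1.0, 1.0) == 0.0
        assert penalty(0.8, 0.7) == pytest.approx(np.sqrt(0.04 + 0.09) + 0.1)
        assert penalty(0.9, 0.5) == pytest.approx(np.sqrt(0.01 + 0.25) + 0.4)

    def test_select_prefers_balanced_gate(self):
        evals = [
            GateEvaluation(parse_gate("A^low"), 0.8, 0.7, penalty(0.8, 0.7), 0, 0, 0, 0),
            GateEvaluation(parse_gate("B^low"), 0.9, 0.5, penalty(0.9, 0.5), 0, 0, 0, 0),
        ]
        assert str(select_best_gate(evals).gate) == "A^low"

    def test_best_gate_is_always_pareto_optimal(self):
        for seed in range(5):
            evals = _random_evals(100, seed)
            pareto_filter(evals)
            assert select_best_gate(evals).pareto

    def test_tie_broken_by_fewer_literals_then_name(self):
        e1 = GateEvaluation(parse_gate("A^low & B^low"), 0.8, 0.8, penalty(0.8, 0.8), 0, 0, 0, 0)
        e2 = GateEvaluation(parse_gate("B^low"), 0.8, 0.8, penalty(0.8, 0.8), 0, 0, 0, 0)
        e3 = GateEvaluation(parse_gate("A^low"), 0.8, 0.8, penalty(0.8, 0.8), 0, 0, 0, 0)
        assert str(select_best_gate([e1, e2, e3]).gate) == "A^low"

    def test_empty_set_rejected(self):
        with pytest.raises(InputError):
            select_best_gate([])
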