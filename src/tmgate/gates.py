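"""Boolean marker gates: parsing, enumeration, evaluation and selection.

A gate is a monotone boolean AND/OR combination of marker literals such as
``CCR7^low & (FLT3LG^low | LTB^low)``. A ``GENE^low`` literal passes for a
cell when the gene's expression is strictly below its threshold (with the
default universal threshold of 0.001 UMI on count data this means "zero
counts"); ``GENE^high`` passes strictly above the threshold.

Enumeration produces every distinct nonconstant monotone boolean function
expressible over up to four literals (counts 1, 4, 18, 166 for 1-4
literals), deduplicated by truth table with a minimal canonical expression
kept per function. Gates are scored by sensitivity (capture rate of true
tumor-matching cells) and specificity (exclusion rate of non-matching
cells); the selection penalty is the Euclidean distance from the perfect
(sensitivity, specificity) = (1, 1) corner plus the absolute
sensitivity-specificity difference, which promotes balanced gates. The
pareto flag marks gates not weakly dominated (with at least one strict
improvement) on both axes.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, InputError

__all__ = [
    "Literal",
    "GateExpression",
    "GateEvalParams",
    "GateEvaluation",
    "parse_gate",
    "enumerate_gates",
    "evaluate_gate",
    "penalty",
    "pareto_filter",
    "select_best_gate",
]

MAX_LITERALS = 4


@dataclass(frozen=True)
class Literal:
    gene: str
    direction: str  # "low" | "high"

    def __post_init__(self) -> None:
        if self.direction not in ("low", "high"):
            raise ConfigError(f"literal direction must be low/high, got {self.direction!r}")

    def __str__(self) -> str:
        return f"{self.gene}^{self.direction}"


class GateExpression:
    """A monotone AND/OR tree over marker literals.

    ``op`` is "lit", "and" or "or"; children are GateExpressions for the
    binary operators. The canonical string renders "&" tighter than "|".
    """

    __slots__ = ("op", "literal", "left", "right")

    def __init__(self, op: str, literal: Optional[Literal] = None,
                 left: "GateExpression | None" = None,
                 right: "GateExpression | None" = None):
        self.op = op
        self.literal = literal
        self.left = left
        self.right = right

    @classmethod
    def lit(cls, gene: str, direction: str) -> "GateExpression":
        return cls("lit", literal=Literal(gene, direction))

    def literals(self) -> tuple[Literal, ...]:
        """Distinct literals, in first-appearance order."""
        seen: dict[Literal, None] = {}

        def walk(node: "GateExpression") -> None:
            if node.op == "lit":
                seen.setdefault(node.literal)
            else:
                walk(node.left)
                walk(node.right)

        walk(self)
        return tuple(seen)

    def evaluate(self, values: Mapping[Literal, np.ndarray]) -> np.ndarray:
        """Vectorised truth value given boolean pass-vectors per literal."""
        if self.op == "lit":
            return np.asarray(values[self.literal], dtype=bool)
        a = self.left.evaluate(values)
        b = self.right.evaluate(values)
        return a & b if self.op == "and" else a | b

    def truth_table(self, literal_order: Sequence[Literal]) -> int:
        """Truth table as a bitmask over all 2^k assignments of the literals."""
        k = len(literal_order)
        assign = {
            literal: np.array([(row >> i) & 1 for row in range(2 ** k)], dtype=bool)
            for i, literal in enumerate(literal_order)
        }
        bits = self.evaluate(assign)
        return int(sum(1 << r for r in np.flatnonzero(bits)))

    def n_nodes(self) -> int:
        if self.op == "lit":
            return 1
        return 1 + self.left.n_nodes() + self.right.n_nodes()

    def __str__(self) -> str:
        if self.op == "lit":
            return str(self.literal)
        parts = []
        for child in (self.left, self.right):
            s = str(child)
            if self.op == "and" and child.op == "or":
                s = f"({s})"
            parts.append(s)
        sep = " & " if self.op == "and" else " | "
        return sep.join(parts)

    def __repr__(self) -> str:
        return f"GateExpression({self})"


_TOKEN_RE = re.compile(r"\s*(?:(?P<lit>[A-Za-z0-9_.\-]+\^(?:low|high))|(?P<op>[&|()])|(?P<bad>\S))")


def parse_gate(text: str) -> GateExpression:
    """Parse the gate mini-language: literals, '&', '|', parentheses.

    '&' binds tighter than '|'. Raises InputError with the offending
    position on a syntax error.
    """
    tokens: list[tuple[str, str, int]] = []
    pos = 0
    while pos < len(text):
        m = _TOKEN_RE.match(text, pos)
        if m is None:
            break
        if m.group("bad"):
            start = m.start("bad")
            rest = text[start:start + 20]
            if re.match(r"[A-Za-z0-9_.\-]+\^", rest):
                raise InputError(f"unknown direction suffix at position {start}: {rest!r} (use ^low or ^high)")
            raise InputError(f"syntax error at position {start}: {rest!r}")
        if m.group("lit"):
            tokens.append(("lit", m.group("lit"), m.start("lit")))
        else:
            tokens.append(("op", m.group("op"), m.start("op")))
        pos = m.end()

    idx = 0

    def peek():
        return tokens[idx] if idx < len(tokens) else None

    def parse_or() -> GateExpression:
        node = parse_and()
        while peek() and peek()[0] == "op" and peek()[1] == "|":
            advance()
            node = GateExpression("or", left=node, right=parse_and())
        return node

    def parse_and() -> GateExpression:
        node = parse_atom()
        while peek() and peek()[0] == "op" and peek()[1] == "&":
            advance()
            node = GateExpression("and", left=node, right=parse_atom())
        return node

    def parse_atom() -> GateExpression:
        tok = peek()
        if tok is None:
            raise InputError(f"syntax error: unexpected end of gate {text!r}")
        if tok[0] == "lit":
            advance()
            gene, direction = tok[1].rsplit("^", 1)
            return GateExpression.lit(gene, direction)
        if tok[1] == "(":
            advance()
            node = parse_or()
            closing = peek()
            if closing is None or closing[1] != ")":
                raise InputError(f"syntax error: unbalanced parenthesis at position {tok[2]}")
            advance()
            return node
        raise InputError(f"syntax error at position {tok[2]}: unexpected {tok[1]!r}")

    def advance():
        nonlocal idx
        idx += 1

    node = parse_or()
    if peek() is not None:
        raise InputError(f"syntax error at position {peek()[2]}: trailing input")
    return node


def enumerate_gates(literals: Sequence[Literal | str]) -> list[GateExpression]:
    """All distinct monotone AND/OR gates over up to 4 literals.

    Gates computing the same monotone boolean function (as a truth table
    over the full literal set) are deduplicated; the representative kept is
    the smallest expression (fewest literal occurrences, then lexicographic
    canonical string). Counts: 1, 4, 18, 166 distinct nonconstant gates for
    1-4 literals.
    """
    lits = [parse_gate(l).literal if isinstance(l, str) else l for l in literals]
    if not 1 <= len(lits) <= MAX_LITERALS:
        raise InputError(f"need 1..{MAX_LITERALS} distinct literals, got {len(lits)}")
    if len(set(lits)) != len(lits):
        raise InputError("literals must be distinct")
    genes_by_dir: dict[str, set[str]] = {}
    for l in lits:
        genes_by_dir.setdefault(l.gene, set()).add(l.direction)
    for gene, dirs in genes_by_dir.items():
        if len(dirs) > 1:
            raise InputError(f"literal {gene} repeated with conflicting directions")

    order = list(lits)
    best: dict[int, GateExpression] = {}

    def key(expr: GateExpression) -> tuple[int, str]:
        return (expr.n_nodes(), str(expr))

    frontier = []
    for l in lits:
        e = GateExpression("lit", literal=l)
        tt = e.truth_table(order)
        best[tt] = e
        frontier.append((tt, e))

    all_items = list(frontier)
    while frontier:
        new = []
        for (t1, e1), (t2, e2) in itertools.product(all_items, frontier):
            for op, tt in (("and", t1 & t2), ("or", t1 | t2)):
                cand = GateExpression(op, left=e1, right=e2)
                if tt not in best or key(cand) < key(best[tt]):
                    is_new = tt not in best
                    best[tt] = cand
                    if is_new:
                        new.append((tt, cand))
        all_items = [(tt, best[tt]) for tt in best]
        frontier = new
    full = (1 << (2 ** len(order))) - 1
    gates = [e for tt, e in best.items() if tt not in (0, full)]
    return sorted(gates, key=key)


@dataclass
class GateEvalParams:
    """Thresholds for literal evaluation.

    ``universal_threshold`` (default 0.001 UMI) applies to every literal
    without an entry in ``thresholds``; on count data any value in (0, 1)
    makes a "low" literal equivalent to zero counts.
    """

    universal_threshold: float = 0.001
    thresholds: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.universal_threshold < 0:
            raise ConfigError("universal_threshold must be >= 0")

    def threshold_for(self, gene: str) -> float:
        return float(self.thresholds.get(gene, self.universal_threshold))


@dataclass
class GateEvaluation:
    gate: GateExpression
    sensitivity: float
    specificity: float
    penalty: float
    tp: int
    fp: int
    tn: int
    fn: int
    pareto: Optional[bool] = None

    @property
    def n_literals(self) -> int:
        return len(self.gate.literals())


def penalty(sensitivity: float, specificity: float) -> float:
    """Distance from the perfect corner plus the balance term."""
    return float(
        np.hypot(1.0 - sensitivity, 1.0 - specificity)
        + abs(sensitivity - specificity)
    )


def evaluate_gate(
    gate: GateExpression,
    expr: pd.DataFrame | Mapping[str, np.ndarray],
    labels: np.ndarray,
    params: GateEvalParams = GateEvalParams(),
) -> GateEvaluation:
    """Sensitivity/specificity/penalty of a gate on labeled cells.

    ``expr`` maps gene -> per-cell expression (a cells x genes DataFrame or
    a plain mapping); raw counts are the intended scale for the default
    UMI threshold semantics. Literal semantics are strict inequalities.
    """
    labels = np.asarray(labels, dtype=bool)
    if labels.all() or not labels.any():
        raise InputError("both classes must be non-empty")
    values: dict[Literal, np.ndarray] = {}
    for lit in gate.literals():
        if isinstance(expr, pd.DataFrame):
            if lit.gene not in expr.columns:
                raise KeyError(f"marker {lit.gene!r} not present")
            x = expr[lit.gene].to_numpy(dtype=float)
        else:
            if lit.gene not in expr:
                raise KeyError(f"marker {lit.gene!r} not present")
            x = np.asarray(expr[lit.gene], dtype=float)
        t = params.threshold_for(lit.gene)
        values[lit] = (x < t) if lit.direction == "low" else (x > t)
    pred = gate.evaluate(values)
    tp = int((pred & labels).sum())
    fn = int((~pred & labels).sum())
    tn = int((~pred & ~labels).sum())
    fp = int((pred & ~labels).sum())
    sens = tp / (tp + fn)
    spec = tn / (tn + fp)
    return GateEvaluation(gate, sens, spec, penalty(sens, spec), tp, fp, tn, fn)


def pareto_filter(evals: Sequence[GateEvaluation]) -> list[bool]:
    """Flag pareto-optimal gates (sets the ``pareto`` field in place too).

    A gate is dominated if another gate is at least as good on both axes and
    strictly better on at least one.
    """
    if len(evals) == 0:
        raise InputError("need at least one evaluation")
    pts = np.array([[e.sensitivity, e.specificity] for e in evals])
    flags = []
    for i, (s, c) in enumerate(pts):
        dominated = (
            (pts[:, 0] >= s) & (pts[:, 1] >= c)
            & ((pts[:, 0] > s) | (pts[:, 1] > c))
        ).any()
        flags.append(not dominated)
    for e, f in zip(evals, flags):
        e.pareto = bool(f)
    return flags


def select_best_gate(evals: Sequence[GateEvaluation]) -> GateEvaluation:
    """The penalty-minimizing gate; ties go to fewer literals, then name."""
    if len(evals) == 0:
        raise InputError("cannot select from an empty evaluation set")
    return min(evals, key=lambda e: (e.penalty, e.n_literals, str(e.gate)))


def evaluations_frame(evals: Sequence[GateEvaluation]) -> pd.DataFrame:
    """Tabular export of a set of gate evaluations."""
    return pd.DataFrame(
        {
            "gate": [str(e.gate) for e in evals],
            "n_literals": [e.n_literals for e in evals],
            "sensitivity": [e.sensitivity for e in evals],
            "specificity": [e.specificity for e in evals],
            "penalty": [e.penalty for e in evals],
            "pareto": [e.pareto for e in evals],
        }
    )
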