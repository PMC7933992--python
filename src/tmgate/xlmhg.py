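"""Exact XL-minimal-hypergeometric (XL-mHG) marker enrichment test.

Given cells ranked by decreasing expression of a gene, and a binary label
(e.g. tumor-matching vs not), the mHG statistic scans every cutoff in the
ranking and takes the smallest hypergeometric upper-tail probability of the
label enrichment above the cutoff. The XL extension constrains the scan:
cutoffs deeper than L ranks are not considered, and a cutoff only counts if
at least X labeled cells lie above it. Because the minimum is an optimised
quantity, the statistic itself is not a p-value; the exact p-value is the
null probability (uniform over all C(N, K) placements of the K labels in
the ranking) that the statistic is at most the observed value, computed by
dynamic programming over the lattice of label-count prefixes.

Hypergeometric tails are evaluated over the whole (cutoff, label-count)
lattice at once from a log-binomial (gammaln) table, which keeps
transcriptome-wide scans fast; the path-counting recursion propagates
hypergeometric transition probabilities and zeroes every lattice cell whose
tail probability reaches the observed statistic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.special import gammaln

from .errors import ConfigError, InputError

__all__ = ["XlmhgParams", "XlmhgResult", "xlmhg_test", "xlmhg_pvalue", "hypergeom_tail_grid"]


@dataclass
class XlmhgParams:
    """Scan constraints: X as a fraction of K, and the L cutoff cap.

    ``x_frac`` — minimum number of labeled cells above an admissible cutoff,
    expressed as a fraction of K (ceil(x_frac * K)); 0.15 by default.
    ``l_rule`` — L = min(10 * K, floor(0.35 * N)) when left None, matching a
    willingness to accept more contamination than the scan's defaults.
    """

    x_frac: float = 0.15
    L: Optional[int] = None

    def __post_init__(self) -> None:
        if not 0 < self.x_frac <= 1:
            raise ConfigError("x_frac must lie in (0, 1]")

    def resolve(self, N: int, K: int) -> tuple[int, int]:
        """Return (X_min, L) for a concrete problem size."""
        x_min = max(1, math.ceil(self.x_frac * K))
        L = self.L if self.L is not None else min(10 * K, math.floor(0.35 * N))
        L = int(min(max(L, 1), N))
        if L < 1:
            raise ConfigError("L must be at least 1")
        return x_min, L


@dataclass
class XlmhgResult:
    """Outcome of one XL-mHG scan (one gene, one direction)."""

    mhg_stat: float
    p: float
    cutoff_rank: Optional[int]  # number of cells above the chosen cutoff
    cutoff_val: float  # absolute expression value at the cutoff
    N: int
    K: int
    X_min: int
    L: int


def hypergeom_tail_grid(N: int, K: int, L: int) -> np.ndarray:
    """Upper-tail grid T[n, b] = P(H >= b), H ~ Hypergeom(N, K, n), for n <= L.

    Shape (L+1, K+1); impossible (n, b) combinations hold 0. Computed from a
    gammaln log-binomial table and a reverse cumulative sum, so the whole
    grid costs one vectorised pass.
    """
    n = np.arange(L + 1)[:, None]
    b = np.arange(K + 1)[None, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        logpmf = (
            _log_binom(K, b)
            + _log_binom(N - K, n - b)
            - _log_binom(N, n)
        )
    feasible = (b <= n) & (n - b <= N - K)
    pmf = np.where(feasible, np.exp(logpmf), 0.0)
    tail = np.cumsum(pmf[:, ::-1], axis=1)[:, ::-1]
    return np.minimum(tail, 1.0)


def _log_binom(n, k):
    n = np.asarray(n, dtype=float)
    k = np.asarray(k, dtype=float)
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def xlmhg_pvalue(N: int, K: int, X_min: int, L: int, stat: float,
                 tail_grid: Optional[np.ndarray] = None) -> float:
    """Exact null probability that the XL-mHG statistic is <= ``stat``.

    Path-counting dynamic programme: walk the ranking one cell at a time,
    tracking the probability mass of label-prefix states (n cells seen,
    b labeled) that have not yet produced a tail probability <= stat within
    the admissible region (n <= L, b >= X_min). The complement of the
    surviving mass is the p-value.
    """
    if K < 1:
        raise InputError("K must be >= 1")
    if stat >= 1.0:
        return 1.0
    T = hypergeom_tail_grid(N, K, L) if tail_grid is None else tail_grid
    # per cutoff depth n, the smallest b whose tail reaches the statistic
    b_arr = np.arange(K + 1)
    w = np.zeros(K + 1)
    w[0] = 1.0
    for n in range(1, N + 1):
        remaining = N - (n - 1)
        p_succ = np.clip((K - b_arr) / remaining, 0.0, 1.0)
        w_new = w * (1.0 - p_succ)
        w_new[1:] += w[:-1] * p_succ[:-1]
        w = w_new
        if n <= L:
            # tolerance: lattice cells sharing one rational tail value can
            # differ in the last ulps of the log-gamma evaluation
            bad = (T[n] <= stat * (1.0 + 1e-10)) & (b_arr >= X_min) & (b_arr <= min(n, K))
            w[bad] = 0.0
    return float(min(max(1.0 - w[K], 0.0), 1.0))


def xlmhg_test(
    expr: np.ndarray,
    labels: np.ndarray,
    params: XlmhgParams = XlmhgParams(),
    direction: str = "positive",
) -> XlmhgResult:
    """Run the XL-mHG scan for one gene.

    ``direction="negation"`` negates the expression vector before ranking, so
    low expression of the gene is what gets tested for label enrichment; the
    reported cutoff value is the absolute expression value either way.
    Cutoffs are only placed between distinct expression values (a cutoff
    inside a tie would be unrealisable as an expression threshold).
    """
    expr = np.asarray(expr, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if expr.shape != labels.shape:
        raise InputError("expr and labels must align")
    N = expr.size
    K = int(labels.sum())
    if K == 0:
        raise InputError("no labeled cells (K = 0)")
    if N < 2:
        raise InputError("need at least 2 cells")
    if direction not in ("positive", "negation"):
        raise ConfigError(f"unknown direction {direction!r}")
    ranked_expr = expr if direction == "positive" else -expr

    order = np.argsort(-ranked_expr, kind="stable")
    sorted_expr = ranked_expr[order]
    sorted_lab = labels[order]
    X_min, L = params.resolve(N, K)

    b_cum = np.cumsum(sorted_lab)
    n_arr = np.arange(1, N + 1)
    # admissible cutoffs: below L, enough labeled cells, and between distinct values
    distinct = np.empty(N, dtype=bool)
    distinct[:-1] = sorted_expr[:-1] > sorted_expr[1:]
    distinct[-1] = True
    admissible = (n_arr <= L) & (b_cum >= X_min) & distinct

    T = hypergeom_tail_grid(N, K, L)
    if not admissible.any():
        return XlmhgResult(1.0, 1.0, None, math.nan, N, K, X_min, L)
    tails = np.full(N, np.inf)
    adm_idx = np.flatnonzero(admissible)
    tails[adm_idx] = T[n_arr[adm_idx], b_cum[adm_idx]]
    best = int(np.argmin(tails))
    stat = float(tails[best])
    if stat >= 1.0:
        return XlmhgResult(1.0, 1.0, None, math.nan, N, K, X_min, L)
    p = xlmhg_pvalue(N, K, X_min, L, stat, tail_grid=T)
    n_top = best + 1
    cutoff_val = float(abs(sorted_expr[n_top])) if n_top < N else float(abs(sorted_expr[-1]))
    return XlmhgResult(stat, p, n_top, cutoff_val, N, K, X_min, L)
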