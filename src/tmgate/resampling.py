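"""Bootstrap confidence intervals and permutation empirical p-values.

Uncertainty for any per-cell statistic (gate sensitivity/specificity,
grid AUC, ...) is quantified by percentile bootstrap over cells
(resampling with replacement at the original size, thresholds held fixed)
and by a permutation null in which each of the B iterations resamples the
cells and then permutes the TM labels within the resample. The empirical
p-value is the fraction of null statistics at least as large as the
observed point estimate; when the observed value is never reached, the
bound 1/B is reported (the "< 0.0001" convention at B = 10,000) rather
than a literal zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Optional

import numpy as np
import pandas as pd

from .errors import InputError

logger = logging.getLogger(__name__)

__all__ = ["ResamplingParams", "ResamplingSummary", "bootstrap_ci", "permutation_p"]

#: statistic evaluator signature: (expr_table, labels) -> float
Statistic = Callable[[pd.DataFrame, np.ndarray], float]


@dataclass
class ResamplingParams:
    B: int = 10_000
    ci: tuple[float, float] = (2.5, 97.5)
    rng_seed: int = 0
    max_redraw: int = 1000  # per-iteration cap on redrawing single-class resamples

    def __post_init__(self) -> None:
        if self.B < 1:
            raise InputError("B must be >= 1")
        lo, hi = self.ci
        if not 0 <= lo < hi <= 100:
            raise InputError("ci percentiles must satisfy 0 <= lo < hi <= 100")


@dataclass
class ResamplingSummary:
    statistic: str
    point: float
    ci_lo: Optional[float] = None
    ci_hi: Optional[float] = None
    empirical_p: Optional[float] = None  # None when never reached (see p_bound)
    p_bound: Optional[str] = None  # e.g. "<0.0001" when the count is zero
    B: int = 0
    seed: int = 0

    def p_display(self) -> str:
        """Empirical p as printed: either the value or the '<1/B' bound."""
        return self.p_bound if self.p_bound is not None else f"{self.empirical_p:g}"


def _resample_indices(rng: np.random.Generator, labels: np.ndarray, params: ResamplingParams) -> tuple[np.ndarray, bool]:
    """Draw a with-replacement resample keeping both classes; report first-try failure."""
    n = labels.size
    idx = rng.integers(0, n, n)
    first_ok = labels[idx].any() and not labels[idx].all()
    tries = 0
    while not (labels[idx].any() and not labels[idx].all()):
        tries += 1
        if tries > params.max_redraw:
            raise InputError("could not draw a two-class resample")
        idx = rng.integers(0, n, n)
    return idx, first_ok


def bootstrap_ci(
    expr: pd.DataFrame,
    labels: np.ndarray,
    statistic: Statistic,
    params: ResamplingParams = ResamplingParams(),
    name: str = "statistic",
) -> ResamplingSummary:
    """Percentile bootstrap CI for a statistic of labeled cells.

    Cells (rows of ``expr``) are resampled with replacement at the original
    size; the statistic is recomputed with all thresholds fixed. Resamples
    that lose a class are redrawn so exactly B valid iterations contribute;
    if more than 10% of first draws are invalid the configuration is
    rejected.
    """
    labels = np.asarray(labels, dtype=bool)
    rng = np.random.default_rng(params.rng_seed)
    point = float(statistic(expr, labels))
    vals = np.empty(params.B)
    n_bad = 0
    for i in range(params.B):
        idx, first_ok = _resample_indices(rng, labels, params)
        n_bad += not first_ok
        vals[i] = statistic(expr.iloc[idx], labels[idx])
    if n_bad > 0.1 * params.B:
        raise InputError(
            f"statistic undefined on {n_bad}/{params.B} first-draw resamples; "
            "class sizes too small for bootstrap"
        )
    lo, hi = np.percentile(vals, params.ci)
    summ = ResamplingSummary(name, point, float(lo), float(hi), B=params.B, seed=params.rng_seed)
    if not lo <= point <= hi:
        logger.warning("percentile CI [%g, %g] excludes the point estimate %g", lo, hi, point)
    return summ


def permutation_p(
    expr: pd.DataFrame,
    labels: np.ndarray,
    statistic: Statistic,
    params: ResamplingParams = ResamplingParams(),
    name: str = "statistic",
) -> ResamplingSummary:
    """Permutation empirical p-value (upper tail) for a statistic.

    Each iteration resamples cells with replacement and permutes the TM
    labels within the resample, building the null of a marker that sorts
    cells by chance alone. p = #{null >= observed} / B; a zero count is
    reported as the bound "< 1/B".
    """
    labels = np.asarray(labels, dtype=bool)
    rng = np.random.default_rng(params.rng_seed)
    point = float(statistic(expr, labels))
    count = 0
    n_bad = 0
    for _ in range(params.B):
        idx, first_ok = _resample_indices(rng, labels, params)
        n_bad += not first_ok
        perm = rng.permutation(labels[idx])
        if statistic(expr.iloc[idx], perm) >= point:
            count += 1
    if n_bad > 0.1 * params.B:
        raise InputError(
            f"statistic undefined on {n_bad}/{params.B} first-draw resamples"
        )
    summ = ResamplingSummary(name, point, B=params.B, seed=params.rng_seed)
    if count == 0:
        summ.p_bound = f"<{1.0 / params.B:g}"
    else:
        summ.empirical_p = count / params.B
    return summ
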