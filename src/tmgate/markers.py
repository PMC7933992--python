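"""Per-gene discriminative statistics for tumor-matching vs non-matching cells.

Two complementary views of each gene are computed, each in a "positive" and
a "negation" direction (high vs low expression predicting TM status):

* a threshold-grid ROC/AUC — 39 candidate expression thresholds (every fifth
  percentile, 21 values, plus 18 evenly spaced values between minimum and
  maximum to cover heavily skewed distributions), with the trivial (0,0) and
  (1,1) operating points appended and AUC by trapezoid integration;
* an exact XL-mHG enrichment test (see :mod:`tmgate.xlmhg`) with
  Benjamini-Hochberg q-values across all genes x directions per sample.

Markers are consolidated across samples by support counting (q below a cut
in at least ``min_samples`` samples, after removing lineage/cytokine
exclusions) and ranked by descending mean AUC. Cross-sample reproducibility
of the AUC profile is summarised by pairwise Pearson correlation with a
seeded coordinate swap (to avoid an arbitrary x-axis bias), stratified into
within- and between-patient sample pairs; cross-species marker overlap is
tested hypergeometrically.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import ConfigError, InputError
from .xlmhg import XlmhgParams, xlmhg_test

logger = logging.getLogger(__name__)

__all__ = [
    "RocGrid",
    "ConsensusParams",
    "SimilarityParams",
    "auc_grid",
    "bh_adjust",
    "marker_scan",
    "consensus_rank",
    "overlap_test",
    "auc_similarity",
]

N_PERCENTILE_THRESHOLDS = 21  # 0th, 5th, ..., 100th
N_LINEAR_THRESHOLDS = 18  # interior points of a 20-point equipartition


@dataclass
class RocGrid:
    """ROC curve of one gene over the 39-threshold grid."""

    gene: str
    direction: str  # "positive" | "negation"
    thresholds: np.ndarray  # the 39 candidate cutoffs
    roc_points: np.ndarray  # (n, 2) array of (1 - specificity, sensitivity)
    auc: float


@dataclass
class ConsensusParams:
    """Cross-sample marker consolidation settings."""

    q_cut: float = 0.05
    min_samples: int = 4
    exclusion_list: Sequence[str] = ("CD8A", "CCL4", "CCL5", "MIF")
    # exclusions: the CD8 lineage marker itself plus cytokines, to restrict
    # candidates to sortable surface markers

    def __post_init__(self) -> None:
        if not 0 < self.q_cut < 1:
            raise ConfigError("q_cut must lie in (0, 1)")


@dataclass
class SimilarityParams:
    """Cross-sample AUC-correlation settings."""

    swap_prob: float = 0.5
    rng_seed: int = 27
    restrict_to: Optional[Sequence[str]] = None

    def __post_init__(self) -> None:
        if not 0 <= self.swap_prob <= 1:
            raise ConfigError("swap_prob must lie in [0, 1]")


def grid_thresholds(expr: np.ndarray) -> np.ndarray:
    """The 39 candidate thresholds for one gene.

    21 linear-interpolation percentiles (0, 5, ..., 100) plus the 18
    interior points of a 20-point equipartition of [min, max]. Duplicates
    are kept: the count is part of the construction.
    """
    expr = np.asarray(expr, dtype=float)
    pct = np.percentile(expr, np.arange(0, 101, 5))
    lin = np.linspace(expr.min(), expr.max(), N_LINEAR_THRESHOLDS + 2)[1:-1]
    return np.concatenate([pct, lin])


def auc_grid(expr: np.ndarray, labels: np.ndarray, gene: str = "",
             direction: str = "positive") -> RocGrid:
    """Grid-based ROC and trapezoid AUC for one gene and direction.

    Positives are cells with expression strictly above the threshold
    (positive direction) or strictly below it (negation). The trivial
    operating points (0,0) and (1,1) are appended before integration; a
    constant gene degenerates to the endpoints alone and AUC 0.5.
    """
    expr = np.asarray(expr, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if labels.all() or not labels.any():
        raise InputError("both classes must be non-empty")
    if direction not in ("positive", "negation"):
        raise ConfigError(f"unknown direction {direction!r}")
    thr = grid_thresholds(expr)
    pos = expr[labels]
    neg = expr[~labels]
    if direction == "positive":
        sens = (pos[None, :] > thr[:, None]).mean(axis=1)
        fpr = (neg[None, :] > thr[:, None]).mean(axis=1)
    else:
        sens = (pos[None, :] < thr[:, None]).mean(axis=1)
        fpr = (neg[None, :] < thr[:, None]).mean(axis=1)
    pts = np.column_stack([fpr, sens])
    pts = np.vstack([pts, [0.0, 0.0], [1.0, 1.0]])
    order = np.lexsort((pts[:, 1], pts[:, 0]))
    pts = pts[order]
    auc = float(np.trapezoid(pts[:, 1], pts[:, 0]))
    return RocGrid(gene=gene, direction=direction, thresholds=thr,
                   roc_points=pts, auc=auc)


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise InputError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def marker_scan(
    expr_matrix: np.ndarray,
    genes: Sequence[str],
    labels: np.ndarray,
    params: XlmhgParams = XlmhgParams(),
    directions: Sequence[str] = ("positive", "negation"),
) -> pd.DataFrame:
    """XL-mHG test + grid AUC for every gene x direction of one sample.

    ``expr_matrix`` is genes x cells (counts or normalized values — the scan
    only uses ranks and thresholds on whatever scale is given). Returns a
    frame with columns gene, direction, mhg_stat, p, q, cutoff_val, auc; the
    BH correction runs across all genes x directions within the sample, and
    the direction column uses the "marker" / "marker_negation" naming of the
    scan's output convention.
    """
    expr_matrix = np.asarray(expr_matrix, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    rows = []
    for gi, gene in enumerate(genes):
        expr = expr_matrix[gi]
        for direction in directions:
            res = xlmhg_test(expr, labels, params, direction=direction)
            grid = auc_grid(expr, labels, gene=gene, direction=direction)
            rows.append(
                {
                    "gene": gene,
                    "direction": "marker" if direction == "positive" else "marker_negation",
                    "mhg_stat": res.mhg_stat,
                    "p": res.p,
                    "cutoff_val": res.cutoff_val,
                    "auc": grid.auc,
                }
            )
    df = pd.DataFrame(rows)
    df["q"] = bh_adjust(df["p"].to_numpy())
    return df[["gene", "direction", "mhg_stat", "p", "q", "cutoff_val", "auc"]]


def consensus_rank(
    results: Mapping[str, pd.DataFrame], params: ConsensusParams = ConsensusParams()
) -> pd.DataFrame:
    """Consolidate per-sample marker tables into a ranked candidate list.

    Keeps (gene, direction) pairs significant (q < q_cut) in at least
    ``min_samples`` samples, drops exclusion-list genes, and ranks by mean
    AUC across samples (descending). The support count is reported.
    """
    if len(results) < 2:
        raise InputError("need marker tables from at least 2 samples")
    frames = []
    for sample, df in results.items():
        sub = df[["gene", "direction", "q", "auc"]].copy()
        sub["sample"] = sample
        frames.append(sub)
    allr = pd.concat(frames, ignore_index=True)
    allr = allr[~allr["gene"].isin(params.exclusion_list)]
    grp = allr.groupby(["gene", "direction"])
    out = grp.agg(
        support=("q", lambda q: int((q < params.q_cut).sum())),
        mean_auc=("auc", "mean"),
        n_samples=("sample", "nunique"),
    ).reset_index()
    out = out[out["support"] >= params.min_samples]
    if len(out) == 0:
        logger.warning("consensus_rank: no marker passed the support threshold")
    out = out.sort_values(["mean_auc", "gene"], ascending=[False, True]).reset_index(drop=True)
    out.insert(0, "rank", np.arange(1, len(out) + 1))
    return out


def overlap_test(set_a: Sequence[str], set_b: Sequence[str], universe: int) -> tuple[int, float]:
    """Hypergeometric upper-tail test for marker-set overlap between species.

    Sets must be drawn from a declared common (homolog-mapped) universe of
    the given size. Returns (overlap size, p).
    """
    a, b = set(set_a), set(set_b)
    if len(a) > universe or len(b) > universe:
        raise InputError("set sizes cannot exceed the universe")
    k = len(a & b)
    if k > min(len(a), len(b)):
        raise InputError("overlap exceeds a set size")
    p = float(stats.hypergeom.sf(k - 1, universe, len(a), len(b)))
    return k, min(p, 1.0)


def auc_similarity(
    auc_tables: Mapping[str, pd.Series],
    patient_of: Mapping[str, str],
    params: SimilarityParams = SimilarityParams(),
) -> pd.DataFrame:
    """Pairwise cross-sample correlation of per-gene AUC profiles.

    For every gene measured in all samples and every unordered sample pair,
    a point (AUC in sample i, AUC in sample j) is formed; x and y are then
    swapped with probability ``swap_prob`` under a fixed seed so neither
    axis is biased toward samples listed first. Pearson R and p are computed
    per stratum: pairs within the same patient vs pairs across patients.
    """
    samples = list(auc_tables)
    if len(samples) < 2:
        raise InputError("need at least 2 samples")
    shared = set.intersection(*(set(s.index) for s in auc_tables.values()))
    if params.restrict_to is not None:
        shared &= set(params.restrict_to)
    shared = sorted(shared)
    if len(shared) < 3:
        raise InputError("fewer than 3 genes shared across all samples")
    rng = np.random.default_rng(params.rng_seed)
    rows = []
    for si, sj in itertools.combinations(samples, 2):
        x = auc_tables[si].loc[shared].to_numpy(dtype=float)
        y = auc_tables[sj].loc[shared].to_numpy(dtype=float)
        swap = rng.random(len(shared)) < params.swap_prob
        x2 = np.where(swap, y, x)
        y2 = np.where(swap, x, y)
        stratum = "within-patient" if patient_of[si] == patient_of[sj] else "between-patient"
        rows.append(pd.DataFrame({"x": x2, "y": y2, "stratum": stratum, "gene": shared}))
    pts = pd.concat(rows, ignore_index=True)
    out = []
    for stratum, sub in pts.groupby("stratum"):
        if len(sub) >= 3 and sub["x"].std() > 0 and sub["y"].std() > 0:
            r, p = stats.pearsonr(sub["x"], sub["y"])
        elif np.allclose(sub["x"], sub["y"]):
            r, p = 1.0, 0.0  # all points on the diagonal (degenerate but defined)
        else:
            r, p = np.nan, np.nan
        out.append({"stratum": stratum, "pearson_r": float(r), "p": float(p), "n_points": len(sub)})
    return pd.DataFrame(out)
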