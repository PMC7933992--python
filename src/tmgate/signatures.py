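"""Gene-signature scoring and group / paired clone-level comparisons.

Scores follow the standard binned-control scheme (the score of a cell is
the mean scaled expression of the signature genes minus the mean of a
control set drawn per expression bin), computed with scanpy's
``score_genes`` on the centered/scaled layer. Cells that are to be compared
must share one bundle so that centering and scaling happen jointly — scores
are relative quantities.

Group comparisons use the Wilcoxon rank-sum test (exact enumeration for
small tie-free groups, normal approximation with tie correction otherwise);
clone-level blood-vs-tumor comparisons use the Wilcoxon signed-rank test on
per-clone mean score differences, restricted to clones detected in both
compartments.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InputError
from .io import SampleBundle

__all__ = [
    "SignatureScoreParams",
    "score_signature",
    "ranksum_compare",
    "paired_clone_compare",
    "clone_signature_summary",
]

EXACT_RANKSUM_MAX = 10  # exact enumeration when both groups are at most this size
EXACT_SIGNRANK_MAX = 15


@dataclass
class SignatureScoreParams:
    n_bins: int = 25
    ctrl_size: int = 50
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_bins < 1 or self.ctrl_size < 1:
            raise InputError("n_bins and ctrl_size must be >= 1")


def score_signature(
    bundle: SampleBundle,
    signature: Sequence[str],
    params: SignatureScoreParams = SignatureScoreParams(),
) -> np.ndarray:
    """Per-cell signature score on the scaled layer.

    Control genes are drawn (seeded) from expression bins of the data-average
    expression, ``ctrl_size`` per signature gene; the score is the mean over
    signature genes minus the mean over controls. Deterministic for a fixed
    seed. Missing signature genes raise (all absent) or warn (partial).
    """
    import anndata as ad
    import scanpy as sc

    if bundle.scaled is None:
        raise InputError("scaled layer required; run normalize_log_tp10k + scale_genes first")
    present = [g for g in signature if g in set(bundle.gene_ids)]
    missing = [g for g in signature if g not in set(bundle.gene_ids)]
    if not present:
        raise InputError(f"signature genes absent from the data: {missing}")
    if missing:
        warnings.warn(f"{len(missing)} signature genes absent, scoring {len(present)}: missing {missing}")
    adata = ad.AnnData(
        X=np.ascontiguousarray(bundle.scaled.T, dtype=np.float64),
        obs=pd.DataFrame(index=bundle.cell_meta.index.astype(str)),
        var=pd.DataFrame(index=pd.Index([str(g) for g in bundle.gene_ids])),
    )
    sc.tl.score_genes(
        adata,
        gene_list=present,
        ctrl_size=params.ctrl_size,
        n_bins=params.n_bins,
        score_name="sig",
        random_state=params.rng_seed,
    )
    return adata.obs["sig"].to_numpy(dtype=float)


def ranksum_compare(scores: np.ndarray, groups: np.ndarray) -> tuple[float, float]:
    """Wilcoxon rank-sum comparison of scores between two groups.

    Returns (U statistic of the True group, two-sided p). Exact enumeration
    when both groups have at most 10 observations and no ties; otherwise the
    normal approximation with midranks and tie correction.
    """
    scores = np.asarray(scores, dtype=float)
    groups = np.asarray(groups, dtype=bool)
    a, b = scores[groups], scores[~groups]
    if a.size == 0 or b.size == 0:
        raise InputError("both groups must be non-empty")
    if np.all(scores == scores[0]):
        return float(a.size * b.size / 2.0), 1.0
    tied = np.unique(scores).size < scores.size
    method = "exact" if (a.size <= EXACT_RANKSUM_MAX and b.size <= EXACT_RANKSUM_MAX and not tied) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method,
                             use_continuity=False)
    return float(res.statistic), float(min(res.pvalue, 1.0))


def clone_signature_summary(
    scores: np.ndarray, clone_ids: Sequence, barcodes: Sequence[str] | None = None
) -> pd.DataFrame:
    """Mean signature score and cell count per clone.

    ``clone_ids`` is a per-cell clone identifier (NaN/None = unclonotyped,
    dropped). One dot per clone, the way clone-level plots are drawn.
    """
    df = pd.DataFrame({"score": np.asarray(scores, dtype=float), "clone": list(clone_ids)})
    df = df[df["clone"].notna()]
    out = df.groupby("clone")["score"].agg(["mean", "size"]).reset_index()
    return out.rename(columns={"mean": "mean_score", "size": "n_cells"})


def paired_clone_compare(
    summary_a: pd.DataFrame, summary_b: pd.DataFrame
) -> tuple[float, float, int]:
    """Wilcoxon signed-rank test on per-clone mean-score differences.

    Inputs are ``clone_signature_summary`` frames for the two conditions
    (e.g. blood vs tumor); the comparison is restricted to clones present in
    both. Zero differences are dropped. Exact p for up to 15 nonzero
    differences, normal approximation beyond. Returns (statistic, p, n used).
    """
    a = summary_a.set_index("clone")["mean_score"]
    b = summary_b.set_index("clone")["mean_score"]
    shared = a.index.intersection(b.index)
    diffs = (a.loc[shared] - b.loc[shared]).to_numpy(dtype=float)
    diffs = diffs[diffs != 0]
    if diffs.size < 2:
        raise InputError("need at least 2 shared clones with nonzero score difference")
    method = "exact" if diffs.size <= EXACT_SIGNRANK_MAX else "approx"
    res = stats.wilcoxon(diffs, zero_method="wilcox", alternative="two-sided", method=method)
    return float(res.statistic), float(min(res.pvalue, 1.0)), int(diffs.size)
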