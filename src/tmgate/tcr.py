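"""Clonotype assignment and blood-tumor TCR matching.

A clonotype is the full set of TCR chains detected in a cell, keyed by
(chain, CDR3 amino-acid sequence) pairs. Two cells belong to the same clone
only if the chain sets are identical — a strict rule that guards against
collapsing distinct clones that merely share one chain. Cells lacking an
annotated alpha or beta chain are excluded from all matching analyses.

A blood cell is "tumor-matching" (TM) when its clonotype also occurs among
tumor cells of the same patient; symmetrically a tumor cell is
"blood-matching" when its clonotype occurs in blood. An alternative
TM definition via external TCR-sequence clustering tools is supported as a
consensus of two algorithms, discarding cells on which they disagree.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InputError
from .io import SampleBundle

logger = logging.getLogger(__name__)

__all__ = [
    "TcrChainRecord",
    "CloneKey",
    "read_contigs",
    "assign_clonotypes",
    "label_matching",
    "consensus_cluster_matching",
    "clone_size_table",
    "expansion_correlation",
    "pseudobulk_by_clone",
]

#: Label vocabulary for matching status.
TM = "TM"
NON_TM = "non-TM"
BLOOD_MATCHING = "blood-matching"
NON_MATCHING = "non-matching"
EXCLUDED = "excluded-no-paired-chains"
CONFLICTED = "conflicted"

CloneKey = tuple  # tuple of (chain, cdr3_aa) pairs, sorted


@dataclass(frozen=True)
class TcrChainRecord:
    cell_barcode: str
    chain: str  # "TRA" | "TRB"
    cdr3_aa: str
    cdr3_nt: Optional[str] = None
    v_gene: Optional[str] = None
    j_gene: Optional[str] = None
    productive: bool = True

    def __post_init__(self) -> None:
        if self.chain not in ("TRA", "TRB"):
            raise InputError(f"chain must be TRA or TRB, got {self.chain!r}")
        if not self.cdr3_aa:
            raise InputError("cdr3_aa must be non-empty")


def read_contigs(path) -> pd.DataFrame:
    """Read a Cell Ranger-style filtered_contig_annotations CSV.

    Only barcode, chain, cdr3 and productive are required; other columns of
    the dialect (is_cell, v_gene, j_gene, cdr3_nt, ...) are carried through
    when present. The productive column accepts True/False or Cell Ranger's
    "True"/"None" strings.
    """
    df = pd.read_csv(path)
    required = {"barcode", "chain", "cdr3"}
    missing = required - set(df.columns)
    if missing:
        raise InputError(f"contig file {path} lacks columns: {sorted(missing)}")
    if "productive" not in df.columns:
        df["productive"] = True
    df["productive"] = df["productive"].map(
        lambda v: str(v).strip().lower() in ("true", "t", "1", "yes")
    )
    return df


def assign_clonotypes(
    chains: pd.DataFrame,
    *,
    include_vj: bool = False,
    include_nonproductive: bool = False,
) -> dict[str, Optional[CloneKey]]:
    """Map each cell barcode to its clonotype key, or None if excluded.

    A cell needs at least one TRA and one TRB chain to receive a key; the key
    is the sorted, deduplicated set of all its detected (chain, cdr3) pairs
    (optionally extended by V/J genes). Non-productive chains are ignored by
    default: they do not define antigen specificity.
    """
    if len(chains) == 0:
        logger.warning("assign_clonotypes: empty chain table")
        return {}
    bad = ~chains["chain"].isin(["TRA", "TRB"])
    if bad.any():
        raise InputError(
            f"malformed chain values: {sorted(chains.loc[bad, 'chain'].unique())}"
        )
    use = chains if include_nonproductive else chains[chains["productive"]]

    out: dict[str, Optional[CloneKey]] = {bc: None for bc in chains["barcode"].unique()}
    for bc, grp in use.groupby("barcode", sort=False):
        if include_vj:
            items = {
                (row.chain, row.cdr3, getattr(row, "v_gene", None), getattr(row, "j_gene", None))
                for row in grp.itertuples()
            }
        else:
            items = {(row.chain, row.cdr3) for row in grp.itertuples()}
        chains_present = {it[0] for it in items}
        if "TRA" in chains_present and "TRB" in chains_present:
            out[bc] = tuple(sorted(items))
    return out


def label_matching(
    blood: Mapping[str, Optional[CloneKey]],
    tumor: Mapping[str, Optional[CloneKey]],
) -> pd.DataFrame:
    """Label blood cells TM / non-TM and tumor cells blood-matching / non-matching.

    Matching is exact identity of clonotype keys across compartments. Cells
    without a paired-chain clonotype are labeled excluded. For multi-resection
    tumors pass the union of their clonotype maps as ``tumor``.
    """
    if blood is None or tumor is None:
        raise InputError("both compartments are required for matching")
    blood_keys = {k for k in blood.values() if k is not None}
    tumor_keys = {k for k in tumor.values() if k is not None}
    rows = []
    for bc, key in blood.items():
        if key is None:
            lab = EXCLUDED
        else:
            lab = TM if key in tumor_keys else NON_TM
        rows.append((bc, "blood", None if key is None else key, lab))
    for bc, key in tumor.items():
        if key is None:
            lab = EXCLUDED
        else:
            lab = BLOOD_MATCHING if key in blood_keys else NON_MATCHING
        rows.append((bc, "tumor", None if key is None else key, lab))
    df = pd.DataFrame(rows, columns=["barcode", "compartment", "clone_key", "label"])
    return df.set_index("barcode")


def consensus_cluster_matching(
    labels_algo1: pd.Series, labels_algo2: pd.Series
) -> tuple[pd.Series, dict]:
    """Combine two cluster-based TM calls; disagreements become 'conflicted'.

    Both inputs are boolean Series over the same blood cells (True = the
    cell's TCR cluster contains at least one tumor TCR under that algorithm).
    Conflicted cells are excluded from downstream statistics.
    """
    if not labels_algo1.index.equals(labels_algo2.index):
        if set(labels_algo1.index) != set(labels_algo2.index):
            raise InputError("the two algorithms must label the same cell set")
        labels_algo2 = labels_algo2.loc[labels_algo1.index]
    agree_tm = labels_algo1 & labels_algo2
    agree_non = ~labels_algo1 & ~labels_algo2
    out = pd.Series(CONFLICTED, index=labels_algo1.index, dtype=object)
    out[agree_tm] = TM
    out[agree_non] = NON_TM
    counts = {
        "TM": int(agree_tm.sum()),
        "non-TM": int(agree_non.sum()),
        "conflicted": int((~agree_tm & ~agree_non).sum()),
    }
    return out, counts


def clone_size_table(
    cells: Mapping[str, Optional[CloneKey]], compartment: Mapping[str, str] | str = "blood"
) -> tuple[pd.DataFrame, pd.Series]:
    """Per-clone cell counts and per-cell clonal-expansion values.

    ``compartment`` may be a single label for all cells or a per-barcode map.
    Returns (clone table with columns clone_id/clone_key/compartment/size,
    per-cell expansion Series = size of the cell's clone; excluded cells NaN).
    """
    comp_of = (lambda bc: compartment) if isinstance(compartment, str) else (lambda bc: compartment[bc])
    recs = [(bc, key, comp_of(bc)) for bc, key in cells.items() if key is not None]
    if not recs:
        return (
            pd.DataFrame(columns=["clone_id", "clone_key", "compartment", "size"]),
            pd.Series(dtype=float),
        )
    # intern clone keys: variable-length tuples are not safe as groupby keys
    key_id: dict[CloneKey, int] = {}
    counts: dict[tuple[int, str], int] = {}
    for _, key, comp in recs:
        cid = key_id.setdefault(key, len(key_id))
        counts[(cid, comp)] = counts.get((cid, comp), 0) + 1
    id_key = {v: k for k, v in key_id.items()}
    sizes = pd.DataFrame(
        [(cid, id_key[cid], comp, n) for (cid, comp), n in counts.items()],
        columns=["clone_id", "clone_key", "compartment", "size"],
    )
    expansion = pd.Series(
        {bc: float(counts[(key_id[key], comp)]) for bc, key, comp in recs},
        dtype=float,
    )
    return sizes, expansion


def expansion_correlation(
    blood_sizes: Mapping[CloneKey, int], tumor_sizes: Mapping[CloneKey, int]
) -> tuple[float, float]:
    """Spearman correlation of log10 clone sizes across compartments.

    Restricted to clones present in both compartments. Returns (rho, p).
    """
    shared = sorted(set(blood_sizes) & set(tumor_sizes), key=repr)
    if len(shared) < 3:
        raise InputError("need at least 3 shared clones for a correlation")
    x = np.log10([blood_sizes[k] for k in shared])
    y = np.log10([tumor_sizes[k] for k in shared])
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


def pseudobulk_by_clone(
    bundle: SampleBundle,
    cells: Mapping[str, Optional[CloneKey]],
    member_barcodes: Iterable[str],
    cpm_min: float = 1.0,
) -> pd.DataFrame:
    """Clone-collapsed counts: sum member cells' counts per clone.

    ``member_barcodes`` selects the label class to aggregate (e.g. the TM
    cells of the blood compartment). Genes are retained only if they reach
    ``cpm_min`` counts per million in the aggregated table — a pre-filter for
    downstream differential-expression tools. Returns a clone x gene frame.
    """
    member = [bc for bc in member_barcodes if cells.get(bc) is not None]
    if not member:
        logger.warning("pseudobulk_by_clone: empty label class")
        return pd.DataFrame(columns=bundle.gene_ids)
    bc_index = {bc: i for i, bc in enumerate(bundle.barcodes)}
    groups: dict[CloneKey, list[int]] = {}
    for bc in member:
        groups.setdefault(cells[bc], []).append(bc_index[bc])
    keys = sorted(groups, key=repr)
    mat = np.vstack([bundle.counts[:, groups[k]].sum(axis=1) for k in keys])
    df = pd.DataFrame(mat, index=pd.Index([repr(k) for k in keys], name="clone_key"),
                      columns=bundle.gene_ids)
    totals = df.to_numpy().sum()
    cpm = df.sum(axis=0) * 1e6 / totals
    return df.loc[:, cpm >= cpm_min]
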