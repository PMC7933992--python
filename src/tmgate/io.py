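"""Core data container and single-cell I/O, QC and normalization.

The central object is :class:`SampleBundle`: one sample's UMI counts
(genes x cells), optional normalized (log TP10K) and scaled
(per-gene z-score) layers, per-cell metadata and gene identifiers.
Reading follows the 10x convention (MatrixMarket MTX plus features/barcodes
TSV); cell metadata is a TSV keyed by barcode.

QC mirrors standard droplet-data practice: a minimum detected-feature count
per cell, a minimum expressing-cell count per gene, a housekeeping-gene
filter (cell kept if it expresses more than half of the list), and a
mitochondrial-gene filter (human: hard cap on the number of expressed
mitochondrial genes; mouse: cells more than ``mouse_mito_sd`` standard
deviations above the across-cell mean are removed). CD8 T cell clusters are
retained by species-specific marker-proportion rules applied to externally
computed cluster labels.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

from .errors import ConfigError, FormatError, InputError

logger = logging.getLogger(__name__)

__all__ = [
    "SampleBundle",
    "QcParams",
    "ClusterRetentionRules",
    "load_sample",
    "write_sample",
    "normalize_log_tp10k",
    "scale_genes",
    "qc_filter_cells",
    "select_cd8_clusters",
    "call_positive",
    "read_gene_list",
]


@dataclass
class SampleBundle:
    """One sample's expression data and per-cell annotations.

    Matrices are oriented genes x cells. ``counts`` holds non-negative
    integer UMI counts; ``normalized`` holds ln(1 + 10000 * c / total);
    ``scaled`` holds per-gene centered, unit-variance values computed over
    the retained cells.
    """

    sample_id: str
    species: str  # "human" or "mouse"
    counts: np.ndarray
    gene_ids: np.ndarray
    cell_meta: pd.DataFrame  # indexed by barcode
    normalized: Optional[np.ndarray] = None
    scaled: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        if self.counts.shape != (len(self.gene_ids), len(self.cell_meta)):
            raise InputError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.cell_meta)} cells"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise InputError("gene_ids must be unique within a sample")
        if self.cell_meta.index.duplicated().any():
            dups = self.cell_meta.index[self.cell_meta.index.duplicated()][:3]
            raise InputError(f"duplicate cell barcodes: {list(dups)}")
        if self.species not in ("human", "mouse"):
            raise ConfigError(f"species must be 'human' or 'mouse', got {self.species!r}")

    @property
    def barcodes(self) -> np.ndarray:
        return self.cell_meta.index.to_numpy()

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_cells(self) -> int:
        return self.counts.shape[1]

    def gene_index(self, gene: str) -> int:
        hits = np.flatnonzero(self.gene_ids == gene)
        if hits.size == 0:
            raise KeyError(f"gene {gene!r} not present in sample {self.sample_id}")
        return int(hits[0])

    def expression(self, gene: str, layer: str = "counts") -> np.ndarray:
        """Per-cell expression vector of one gene from the given layer."""
        mat = getattr(self, layer)
        if mat is None:
            raise InputError(f"layer {layer!r} not computed yet")
        return np.asarray(mat[self.gene_index(gene)])

    def subset_cells(self, mask: np.ndarray) -> "SampleBundle":
        mask = np.asarray(mask, dtype=bool)
        return replace(
            self,
            counts=self.counts[:, mask],
            normalized=None if self.normalized is None else self.normalized[:, mask],
            scaled=None if self.scaled is None else self.scaled[:, mask],
            cell_meta=self.cell_meta.loc[mask].copy(),
        )

    def subset_genes(self, mask: np.ndarray) -> "SampleBundle":
        mask = np.asarray(mask, dtype=bool)
        return replace(
            self,
            counts=self.counts[mask],
            normalized=None if self.normalized is None else self.normalized[mask],
            scaled=None if self.scaled is None else self.scaled[mask],
            gene_ids=self.gene_ids[mask],
        )


@dataclass
class QcParams:
    """Cell-level QC thresholds.

    ``min_features``: minimum detected genes per cell (cell kept if >= value).
    ``min_cells_per_gene``: minimum expressing cells per gene.
    ``housekeeping_genes``: cell kept if it expresses (count > 0) strictly
    more than half of this list.
    ``mito_genes``: human cells removed if they express more than
    ``human_mito_cap`` of these; mouse cells removed if their expressed-gene
    count exceeds mean + ``mouse_mito_sd`` * SD across cells.
    """

    min_features: int = 400
    min_cells_per_gene: int = 3
    housekeeping_genes: Sequence[str] = ()
    mito_genes: Sequence[str] = ()
    human_mito_cap: int = 500
    mouse_mito_sd: float = 2.0

    def __post_init__(self) -> None:
        if self.min_features < 0 or self.min_cells_per_gene < 0:
            raise ConfigError("QC thresholds must be non-negative")
        if self.human_mito_cap < 0 or self.mouse_mito_sd < 0:
            raise ConfigError("mitochondrial thresholds must be non-negative")


@dataclass
class ClusterRetentionRules:
    """Marker-proportion rules deciding which clusters are CD8 T cells.

    Human clusters are kept if (a) the proportion of cells expressing at
    least two of CD3E/CD3D/CD3G exceeds ``cd3_prop`` AND either
    (b) CD8B or CD8A is expressed in more than ``cd8_prop`` of cells while
    FOXP3 and CD4 are each expressed in less than ``treg_cap`` of cells, or
    (c) MKI67 is expressed in more than ``mki67_prop`` of cells and CD8A or
    CD8B in more than ``cycling_cd8_prop`` (proliferating clusters).
    Mouse clusters are kept if more than ``cd3_prop`` of cells express any
    of Cd3e/Cd3d/Cd3g, more than ``cd8_prop`` co-express Cd3e and Cd8a, and
    fewer than ``treg_cap`` express Foxp3.
    """

    cd3_prop: float = 0.30
    cd8_prop: float = 0.30
    treg_cap: float = 0.05
    mki67_prop: float = 0.70
    cycling_cd8_prop: float = 0.20

    def __post_init__(self) -> None:
        for v in (self.cd3_prop, self.cd8_prop, self.treg_cap,
                  self.mki67_prop, self.cycling_cd8_prop):
            if not 0.0 <= v <= 1.0:
                raise ConfigError("retention proportions must lie in [0, 1]")


def _open_maybe_gz(path: Path):
    if str(path).endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path)


def _read_lines(path: Path) -> list[str]:
    with _open_maybe_gz(path) as fh:
        return [line.rstrip("\n").split("\t")[0] for line in fh if line.strip()]


def read_gene_list(path) -> list[str]:
    """Read a gene list: one symbol per line, or GMT (symbols from field 3 on)."""
    path = Path(path)
    with _open_maybe_gz(path) as fh:
        lines = [line.rstrip("\n") for line in fh if line.strip()]
    if path.suffix.lower() == ".gmt" or (lines and lines[0].count("\t") >= 2):
        genes: list[str] = []
        for line in lines:
            genes.extend(line.split("\t")[2:])
        return genes
    return [line.split("\t")[0] for line in lines]


def load_sample(
    counts_path,
    features_path,
    barcodes_path,
    meta_path=None,
    *,
    sample_id: str = "sample",
    species: str = "human",
    genes_as_rows: bool = True,
    min_features: int = 400,
    min_cells_per_gene: int = 3,
) -> SampleBundle:
    """Read a 10x-style MTX triple (+ optional metadata TSV) into a bundle.

    Genes with fewer than ``min_cells_per_gene`` expressing cells and cells
    with fewer than ``min_features`` detected genes are dropped (both masks
    computed on the raw matrix); the drop counts are logged.
    """
    counts_path, features_path, barcodes_path = map(Path, (counts_path, features_path, barcodes_path))
    try:
        mat = spio.mmread(str(counts_path))
    except Exception as exc:  # malformed MTX
        raise FormatError(f"cannot parse MatrixMarket file {counts_path}: {exc}") from exc
    mat = sparse.coo_matrix(mat)
    if not genes_as_rows:
        mat = mat.T
    counts = np.asarray(mat.todense())

    genes = _read_lines(features_path)
    barcodes = _read_lines(barcodes_path)
    if counts.shape[0] != len(genes):
        raise FormatError(
            f"{counts_path} declares {counts.shape[0]} genes but "
            f"{features_path} lists {len(genes)}"
        )
    if counts.shape[1] != len(barcodes):
        raise FormatError(
            f"{counts_path} declares {counts.shape[1]} cells but "
            f"{barcodes_path} lists {len(barcodes)}"
        )
    if len(set(barcodes)) != len(barcodes):
        raise InputError(f"duplicate barcodes in {barcodes_path}")
    if (counts < 0).any() or not np.allclose(counts, np.round(counts)):
        raise InputError("counts must be non-negative integers")
    counts = counts.astype(np.int64)

    meta = pd.DataFrame(index=pd.Index(barcodes, name="barcode"))
    if meta_path is not None:
        ext = pd.read_csv(meta_path, sep="\t", dtype=str)
        if "barcode" not in ext.columns:
            raise FormatError(f"{meta_path} lacks a 'barcode' column")
        ext = ext.set_index("barcode")
        missing = set(barcodes) - set(ext.index)
        if missing:
            raise InputError(f"{len(missing)} barcodes missing from metadata, e.g. {sorted(missing)[:3]}")
        meta = ext.loc[barcodes].copy()
        meta.index.name = "barcode"

    gene_mask = (counts > 0).sum(axis=1) >= min_cells_per_gene
    cell_mask = (counts > 0).sum(axis=0) >= min_features
    logger.info(
        "load_sample %s: dropped %d/%d genes (<%d cells), %d/%d cells (<%d features)",
        sample_id, int((~gene_mask).sum()), counts.shape[0], min_cells_per_gene,
        int((~cell_mask).sum()), counts.shape[1], min_features,
    )
    bundle = SampleBundle(
        sample_id=sample_id,
        species=species,
        counts=counts,
        gene_ids=np.asarray(genes, dtype=object),
        cell_meta=meta,
    )
    return bundle.subset_genes(gene_mask).subset_cells(cell_mask)


def write_sample(bundle: SampleBundle, out_dir) -> dict:
    """Write counts as MTX plus features/barcodes/metadata TSVs; return the paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "counts": out / "matrix.mtx",
        "features": out / "features.tsv",
        "barcodes": out / "barcodes.tsv",
        "meta": out / "cell_meta.tsv",
    }
    spio.mmwrite(str(paths["counts"]), sparse.coo_matrix(bundle.counts))
    paths["features"].write_text("".join(f"{g}\n" for g in bundle.gene_ids))
    paths["barcodes"].write_text("".join(f"{b}\n" for b in bundle.barcodes))
    bundle.cell_meta.reset_index().to_csv(paths["meta"], sep="\t", index=False)
    return {k: str(v) for k, v in paths.items()}


def normalize_log_tp10k(bundle: SampleBundle) -> SampleBundle:
    """Populate the normalized layer: ln(1 + 10000 * c / cell_total)."""
    totals = bundle.counts.sum(axis=0)
    if (totals == 0).any():
        raise InputError("cells with zero total counts present; run QC filtering first")
    norm = np.log1p(1e4 * bundle.counts / totals[None, :])
    return replace(bundle, normalized=norm)


def scale_genes(bundle: SampleBundle, layer: str = "normalized") -> SampleBundle:
    """Populate the scaled layer: per-gene zero mean, unit variance.

    Genes with zero variance over the retained cells become all-zero.
    Scaling is meant to run after QC and CD8 selection, on the cells that
    will actually be compared.
    """
    src = getattr(bundle, layer)
    if src is None:
        raise InputError(f"layer {layer!r} not computed yet")
    mu = src.mean(axis=1, keepdims=True)
    sd = src.std(axis=1, ddof=0, keepdims=True)
    sd_safe = np.where(sd > 0, sd, 1.0)
    scaled = (src - mu) / sd_safe
    scaled[np.squeeze(sd, axis=1) == 0, :] = 0.0
    return replace(bundle, scaled=scaled)


def _expressed_count(bundle: SampleBundle, genes: Sequence[str]) -> tuple[np.ndarray, int]:
    """Per-cell number of listed genes with count > 0; also the usable list size."""
    idx = [np.flatnonzero(bundle.gene_ids == g) for g in genes]
    rows = [int(i[0]) for i in idx if i.size]
    n_used = len(rows)
    if n_used == 0:
        return np.zeros(bundle.n_cells, dtype=int), 0
    return (bundle.counts[rows] > 0).sum(axis=0), n_used


def qc_filter_cells(bundle: SampleBundle, params: QcParams) -> tuple[SampleBundle, dict]:
    """Apply housekeeping and mitochondrial filters; return bundle + removal report.

    Housekeeping: keep cells expressing strictly more than half of the list.
    Mitochondrial — human: keep cells expressing <= ``human_mito_cap`` of the
    list; mouse: keep cells whose expressed-mito count is at most
    mean + ``mouse_mito_sd`` * SD (one-sided; high mitochondrial content flags
    damaged cells). A zero across-cell SD removes nobody.
    """
    if bundle.species not in ("human", "mouse"):
        raise ConfigError("species must be set before QC")
    keep = np.ones(bundle.n_cells, dtype=bool)
    report = {"n_in": bundle.n_cells}

    if len(params.housekeeping_genes) > 0:
        hk_counts, n_hk = _expressed_count(bundle, params.housekeeping_genes)
        if n_hk == 0:
            raise ConfigError("none of the housekeeping genes are in the matrix")
        hk_pass = hk_counts > (len(params.housekeeping_genes) / 2.0)
        report["removed_housekeeping"] = int((~hk_pass & keep).sum())
        keep &= hk_pass

    if len(params.mito_genes) > 0:
        mito_counts, n_mito = _expressed_count(bundle, params.mito_genes)
        if n_mito == 0:
            raise ConfigError("none of the mitochondrial genes are in the matrix")
        if bundle.species == "human":
            mito_pass = mito_counts <= params.human_mito_cap
        else:
            sd = mito_counts[keep].std(ddof=0) if keep.any() else 0.0
            mean = mito_counts[keep].mean() if keep.any() else 0.0
            mito_pass = mito_counts <= mean + params.mouse_mito_sd * sd if sd > 0 else np.ones_like(keep)
        report["removed_mito"] = int((~mito_pass & keep).sum())
        keep &= mito_pass

    report["n_out"] = int(keep.sum())
    return bundle.subset_cells(keep), report


def _cluster_prop(counts: np.ndarray, gene_ids: np.ndarray, gene: str, cells: np.ndarray) -> float:
    """Proportion of the given cells with count > 0; absent gene counts as 0."""
    hits = np.flatnonzero(gene_ids == gene)
    if hits.size == 0:
        return 0.0
    return float((counts[int(hits[0]), cells] > 0).mean())


def select_cd8_clusters(
    bundle: SampleBundle, rules: ClusterRetentionRules = ClusterRetentionRules()
) -> tuple[SampleBundle, dict]:
    """Keep cells in clusters passing the species' CD8 retention rules.

    Requires a ``cluster`` column in ``cell_meta`` (labels computed by an
    external clustering step). Returns the filtered bundle and a report of
    kept / dropped cluster identities.
    """
    if "cluster" not in bundle.cell_meta.columns or bundle.cell_meta["cluster"].isna().any():
        raise InputError("every cell must carry a cluster label")
    clusters = bundle.cell_meta["cluster"].to_numpy()
    kept_clusters, dropped_clusters = [], []
    prop = lambda gene, cells: _cluster_prop(bundle.counts, bundle.gene_ids, gene, cells)

    for cl in pd.unique(clusters):
        cells = np.flatnonzero(clusters == cl)
        if bundle.species == "human":
            cd3_genes = ["CD3E", "CD3D", "CD3G"]
            rows = [np.flatnonzero(bundle.gene_ids == g) for g in cd3_genes]
            rows = [int(r[0]) for r in rows if r.size]
            n_cd3 = (bundle.counts[rows][:, cells] > 0).sum(axis=0) if rows else np.zeros(len(cells))
            rule_a = float((n_cd3 >= 2).mean()) > rules.cd3_prop
            rule_b = (
                (prop("CD8B", cells) > rules.cd8_prop or prop("CD8A", cells) > rules.cd8_prop)
                and prop("FOXP3", cells) < rules.treg_cap
                and prop("CD4", cells) < rules.treg_cap
            )
            rule_c = prop("MKI67", cells) > rules.mki67_prop and (
                prop("CD8A", cells) > rules.cycling_cd8_prop
                or prop("CD8B", cells) > rules.cycling_cd8_prop
            )
            keep = rule_a and (rule_b or rule_c)
        else:
            any_cd3 = max(prop(g, cells) for g in ("Cd3e", "Cd3d", "Cd3g"))
            rows = [np.flatnonzero(bundle.gene_ids == g) for g in ("Cd3e", "Cd8a")]
            if all(r.size for r in rows):
                co = ((bundle.counts[int(rows[0][0]), cells] > 0)
                      & (bundle.counts[int(rows[1][0]), cells] > 0)).mean()
            else:
                co = 0.0
            keep = (
                any_cd3 > rules.cd3_prop
                and float(co) > rules.cd8_prop
                and prop("Foxp3", cells) < rules.treg_cap
            )
        (kept_clusters if keep else dropped_clusters).append(cl)

    mask = np.isin(clusters, kept_clusters)
    report = {"kept": list(kept_clusters), "dropped": list(dropped_clusters)}
    return bundle.subset_cells(mask), report


def call_positive(
    bundle: SampleBundle, gene: str, threshold: float = 0.0, layer: str = "counts"
) -> np.ndarray:
    """Per-cell positivity: strictly above ``threshold`` on the given layer.

    With the default threshold 0 on counts this is the conventional
    "any reads > 0" transcript-positivity call; a COMET-derived cutoff can be
    passed instead for more stringent calls.
    """
    if threshold < 0:
        raise ConfigError("threshold must be >= 0")
    return bundle.expression(gene, layer=layer) > threshold
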