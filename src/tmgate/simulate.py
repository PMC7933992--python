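"""Synthetic paired blood/tumor single-cell data with planted ground truth.

The generator emulates the data shape the pipeline consumes: two
compartments of CD8 T cells with a clonal structure (geometric clone-size
law), a configurable fraction of blood cells belonging to clones that also
seed the tumor (the planted tumor-matching component), negative-binomial
UMI counts with log-normal gene means, marker genes shifted between TM and
non-TM blood cells by stated log2 fold changes, extra dropout, and per-cell
TCR chain records in the Cell Ranger contig dialect — including clones
carrying two alpha or two beta chains, cells with a missing locus, and
occasional non-productive contigs.

All randomness flows from a single seed through named SeedSequence child
streams (clones, counts, dropout, chains, truth), so each stage is
reproducible on its own and outputs are byte-identical across runs.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, InputError
from .gates import GateExpression, Literal, parse_gate
from .io import SampleBundle, write_sample

__all__ = [
    "MarkerSpec",
    "SimConfig",
    "GroundTruth",
    "SimulatedSample",
    "simulate_paired_sample",
    "planted_gate_dataset",
    "write_outputs",
]

_AA = "ACDEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True)
class MarkerSpec:
    """One planted marker: signed log2 fold change of TM vs non-TM blood cells.

    Negative values make the gene a negation marker (low expression marks
    TM cells), matching the character of the top consensus markers.
    ``base_mean`` fixes the non-TM mean expression instead of drawing it
    from the gene-mean law: an informative negation marker must be
    appreciably expressed in the background population (the way CCR7 or LTB
    are in naive blood T cells), otherwise its absence carries no signal.
    """

    gene: str
    log2fc: float
    base_mean: Optional[float] = 4.0

    @property
    def direction(self) -> str:
        return "positive" if self.log2fc >= 0 else "negation"


def _default_markers() -> tuple[MarkerSpec, ...]:
    return tuple(MarkerSpec(f"MARK{i+1}", -1.5) for i in range(4))


@dataclass
class SimConfig:
    """Study-shaped simulation settings.

    Defaults describe one mid-sized sample pair: 2,000 blood and 1,500 tumor
    CD8 cells, 200 genes, 10% of blood cells in tumor-shared clones,
    geometric clone sizes with mean 2.5 cells, log-normal gene means
    (median ~0.6 UMI), negative-binomial dispersion theta = 2, 5% extra
    dropout, and 4 planted negation markers at |log2FC| = 1.5.
    """

    n_blood: int = 2000
    n_tumor: int = 1500
    n_genes: int = 200
    markers: tuple[MarkerSpec, ...] = field(default_factory=_default_markers)
    shared_clone_fraction: float = 0.1
    clone_size_p: float = 0.4  # geometric success prob; mean size 1/p
    nb_mean_log_mu: float = -0.5
    nb_mean_log_sd: float = 1.2
    nb_dispersion: float = 2.0  # NB shape theta; var = mu + mu^2/theta
    dropout_extra: float = 0.05
    multi_chain_fraction: float = 0.08
    missing_chain_fraction: float = 0.10
    nonproductive_fraction: float = 0.05
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("shared_clone_fraction", "dropout_extra", "multi_chain_fraction",
                     "missing_chain_fraction", "nonproductive_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must lie in [0, 1], got {v}")
        if self.n_blood < 1 or self.n_tumor < 1 or self.n_genes < 1:
            raise ConfigError("cell and gene counts must be >= 1")
        if self.nb_dispersion <= 0:
            raise ConfigError("nb_dispersion must be positive")
        if not 0 < self.clone_size_p <= 1:
            raise ConfigError("clone_size_p must lie in (0, 1]")
        if len({m.gene for m in self.markers}) != len(self.markers):
            raise ConfigError("marker gene names must be unique")
        if len(self.markers) > self.n_genes:
            raise ConfigError("more markers than genes")


@dataclass
class GroundTruth:
    """Planted truth for one simulated sample pair."""

    tm_blood: pd.Series  # barcode -> bool, blood cells
    matching_tumor: pd.Series  # barcode -> bool, tumor cells
    clone_of: pd.Series  # barcode -> clone id (all cells)
    clone_table: pd.DataFrame  # clone_id, blood_size, tumor_size, shared
    marker_truth: pd.DataFrame  # gene, log2fc, direction, auc_mc

    def to_json(self) -> str:
        payload = {
            "tm_blood": {k: bool(v) for k, v in self.tm_blood.items()},
            "matching_tumor": {k: bool(v) for k, v in self.matching_tumor.items()},
            "clone_of": {k: int(v) for k, v in self.clone_of.items()},
            "clone_table": self.clone_table.to_dict(orient="records"),
            "marker_truth": self.marker_truth.to_dict(orient="records"),
        }
        return json.dumps(payload, sort_keys=True)


@dataclass
class SimulatedSample:
    bundle: SampleBundle  # blood + tumor cells, compartment column set
    chains: pd.DataFrame  # contig-dialect records
    truth: GroundTruth
    config: SimConfig


def _clone_sizes(rng: np.random.Generator, n_cells: int, p: float) -> np.ndarray:
    """Geometric clone sizes trimmed so they sum exactly to n_cells."""
    sizes: list[int] = []
    total = 0
    while total < n_cells:
        s = int(rng.geometric(p))
        sizes.append(s)
        total += s
    sizes[-1] -= total - n_cells
    if sizes[-1] == 0:
        sizes.pop()
    return np.array(sizes, dtype=int)


def _pick_shared(rng: np.random.Generator, sizes: np.ndarray, target_cells: float) -> np.ndarray:
    """Random clone subset whose total size lands next to target_cells."""
    order = rng.permutation(len(sizes))
    chosen: list[int] = []
    total = 0
    for idx in order:
        if total >= target_cells:
            break
        # include unless stopping now is strictly closer to the target
        if abs(total + sizes[idx] - target_cells) <= abs(total - target_cells):
            chosen.append(idx)
            total += sizes[idx]
        else:
            break
    return np.array(sorted(chosen), dtype=int)


def _nb_counts(rng: np.random.Generator, mean: np.ndarray, theta: float) -> np.ndarray:
    p = theta / (theta + mean)
    return rng.negative_binomial(theta, p)


def _random_cdr3(rng: np.random.Generator, used: set[str]) -> str:
    while True:
        L = int(rng.integers(8, 21))
        body = "".join(_AA[i] for i in rng.integers(0, len(_AA), L - 2))
        s = "C" + body + "F"
        if s not in used:
            used.add(s)
            return s


def _mc_auc(rng: np.random.Generator, mu_pos: float, mu_neg: float, theta: float,
            dropout: float, n: int = 20000) -> float:
    """Monte-Carlo AUC of the marker's TM vs non-TM count distributions."""
    a = _nb_counts(rng, np.full(n, mu_pos), theta).astype(float)
    b = _nb_counts(rng, np.full(n, mu_neg), theta).astype(float)
    if dropout > 0:
        a[rng.random(n) < dropout] = 0
        b[rng.random(n) < dropout] = 0
    bs = np.sort(b)
    gt = np.searchsorted(bs, a, side="left")
    ge = np.searchsorted(bs, a, side="right")
    return float((gt + 0.5 * (ge - gt)).mean() / n)


def simulate_paired_sample(config: SimConfig = SimConfig(),
                           sample_id: str = "SIM", patient_id: str = "P1") -> SimulatedSample:
    """Generate one paired blood/tumor sample with planted TM structure."""
    ss = np.random.SeedSequence(config.rng_seed)
    rng_clone, rng_counts, rng_drop, rng_chain, rng_truth = (
        np.random.default_rng(c) for c in ss.spawn(5)
    )

    blood_sizes = _clone_sizes(rng_clone, config.n_blood, config.clone_size_p)
    shared_idx = _pick_shared(rng_clone, blood_sizes,
                              config.shared_clone_fraction * config.n_blood)
    n_blood_clones = len(blood_sizes)

    # tumor: shared clones first, then private tumor clones up to n_tumor
    if len(shared_idx) > config.n_tumor:
        raise InputError(
            f"infeasible config: {len(shared_idx)} shared clones cannot fit "
            f"in {config.n_tumor} tumor cells"
        )
    shared_tumor_sizes = rng_clone.geometric(config.clone_size_p, len(shared_idx)).astype(int)
    while shared_tumor_sizes.sum() > config.n_tumor:
        shared_tumor_sizes[np.argmax(shared_tumor_sizes)] -= 1  # every shared clone keeps >= 1 cell
    n_private_tumor = config.n_tumor - int(shared_tumor_sizes.sum())
    private_tumor_sizes = (
        _clone_sizes(rng_clone, n_private_tumor, config.clone_size_p)
        if n_private_tumor > 0 else np.array([], dtype=int)
    )

    # clone ids: blood clones 0..n_blood_clones-1; private tumor clones after
    clone_ids_blood = np.repeat(np.arange(n_blood_clones), blood_sizes)
    tumor_clone_ids = np.concatenate([
        np.repeat(shared_idx, shared_tumor_sizes),
        np.repeat(np.arange(len(private_tumor_sizes)) + n_blood_clones, private_tumor_sizes),
    ]).astype(int)
    n_clones = n_blood_clones + len(private_tumor_sizes)

    shared_set = set(int(i) for i in shared_idx)
    tm_blood = np.isin(clone_ids_blood, shared_idx)
    matching_tumor = np.isin(tumor_clone_ids, shared_idx)

    barcodes_blood = [f"B{i:05d}" for i in range(config.n_blood)]
    barcodes_tumor = [f"T{i:05d}" for i in range(config.n_tumor)]
    n_total = config.n_blood + config.n_tumor

    genes = [m.gene for m in config.markers] + [
        f"G{i:04d}" for i in range(config.n_genes - len(config.markers))
    ]
    base_mean = rng_counts.lognormal(config.nb_mean_log_mu, config.nb_mean_log_sd,
                                     config.n_genes)
    for mi, spec in enumerate(config.markers):
        if spec.base_mean is not None:
            base_mean[mi] = spec.base_mean
    mean_mat = np.tile(base_mean[:, None], (1, n_total)).astype(float)
    for mi, spec in enumerate(config.markers):
        cols = np.flatnonzero(tm_blood)  # effects applied in blood TM cells only
        mean_mat[mi, cols] *= 2.0 ** spec.log2fc
    counts = _nb_counts(rng_counts, mean_mat, config.nb_dispersion).astype(np.int64)
    if config.dropout_extra > 0:
        counts[rng_drop.random(counts.shape) < config.dropout_extra] = 0

    meta = pd.DataFrame(
        {
            "sample_id": sample_id,
            "patient_id": patient_id,
            "compartment": ["blood"] * config.n_blood + ["tumor"] * config.n_tumor,
        },
        index=pd.Index(barcodes_blood + barcodes_tumor, name="barcode"),
    )
    bundle = SampleBundle(
        sample_id=sample_id, species="human",
        counts=counts, gene_ids=np.asarray(genes, dtype=object), cell_meta=meta,
    )

    chains = _simulate_chains(
        rng_chain, config, clone_ids_blood, tumor_clone_ids, n_clones,
        barcodes_blood, barcodes_tumor,
    )

    marker_rows = []
    for mi, spec in enumerate(config.markers):
        # AUC of the positive direction; values < 0.5 flag negation markers
        auc = _mc_auc(rng_truth, base_mean[mi] * 2.0 ** spec.log2fc, base_mean[mi],
                      config.nb_dispersion, config.dropout_extra)
        marker_rows.append({"gene": spec.gene, "log2fc": spec.log2fc,
                            "direction": spec.direction, "auc_mc": auc})

    clone_table = pd.DataFrame({
        "clone_id": np.arange(n_clones),
        "blood_size": np.bincount(clone_ids_blood, minlength=n_clones),
        "tumor_size": np.bincount(tumor_clone_ids, minlength=n_clones),
    })
    clone_table["shared"] = clone_table["clone_id"].isin(list(shared_set))

    truth = GroundTruth(
        tm_blood=pd.Series(tm_blood, index=barcodes_blood),
        matching_tumor=pd.Series(matching_tumor, index=barcodes_tumor),
        clone_of=pd.Series(
            np.concatenate([clone_ids_blood, tumor_clone_ids]),
            index=barcodes_blood + barcodes_tumor,
        ),
        clone_table=clone_table,
        marker_truth=pd.DataFrame(marker_rows),
    )
    return SimulatedSample(bundle=bundle, chains=chains, truth=truth, config=config)


def _simulate_chains(
    rng: np.random.Generator,
    config: SimConfig,
    clone_ids_blood: np.ndarray,
    tumor_clone_ids: np.ndarray,
    n_clones: int,
    barcodes_blood: list[str],
    barcodes_tumor: list[str],
) -> pd.DataFrame:
    """Per-cell contig records; clone chain sets are fixed per clone."""
    used: set[str] = set()
    clone_chains: list[list[tuple[str, str]]] = []
    multi = rng.random(n_clones) < config.multi_chain_fraction
    for ci in range(n_clones):
        ch = [("TRA", _random_cdr3(rng, used)), ("TRB", _random_cdr3(rng, used))]
        if multi[ci]:
            extra_locus = "TRA" if rng.random() < 0.5 else "TRB"
            ch.append((extra_locus, _random_cdr3(rng, used)))
        clone_chains.append(ch)

    rows = []
    for bc, ci in zip(
        barcodes_blood + barcodes_tumor,
        np.concatenate([clone_ids_blood, tumor_clone_ids]),
    ):
        ch = list(clone_chains[int(ci)])
        if rng.random() < config.missing_chain_fraction:
            drop_locus = "TRA" if rng.random() < 0.5 else "TRB"
            ch = [c for c in ch if c[0] != drop_locus]
        for locus, cdr3 in ch:
            rows.append((bc, True, True, locus, cdr3, True))
        if rng.random() < config.nonproductive_fraction:
            locus = "TRA" if rng.random() < 0.5 else "TRB"
            rows.append((bc, True, True, locus, _random_cdr3(rng, used), False))
    return pd.DataFrame(
        rows, columns=["barcode", "is_cell", "high_confidence", "chain", "cdr3", "productive"]
    )


def planted_gate_dataset(
    config: SimConfig,
    gate: GateExpression | str,
    label_noise: float = 0.05,
    literal_probs: Optional[dict[str, float]] = None,
) -> tuple[SampleBundle, np.ndarray, GateExpression]:
    """Blood cells whose TM labels realise a planted boolean gate.

    Each literal's pass state is drawn independently (probability 0.5 per
    cell unless overridden per gene in ``literal_probs``); marker counts
    are set so the zero/nonzero pattern realises the state under the
    universal 0.001-UMI threshold; the TM label is the planted gate's truth
    value with ``label_noise`` of labels flipped. Background genes follow
    the usual negative-binomial model. When recovery of the planted gate by
    penalty minimisation is the point, pick literal probabilities that make
    the gate fire for about half the cells: symmetric label noise then
    leaves the planted gate both closest to the perfect corner and balanced.
    Returns (bundle, labels, parsed gate).
    """
    gate = parse_gate(gate) if isinstance(gate, str) else gate
    lits = gate.literals()
    if len(lits) > 4:
        raise InputError("planted gates use at most 4 literals")
    marker_genes = {m.gene for m in config.markers}
    missing = [l.gene for l in lits if l.gene not in marker_genes]
    if missing:
        raise InputError(f"gate references unsimulated markers: {missing}")
    if not 0.0 <= label_noise <= 1.0:
        raise ConfigError("label_noise must lie in [0, 1]")

    ss = np.random.SeedSequence(config.rng_seed)
    rng_state, rng_counts, rng_noise = (np.random.default_rng(c) for c in ss.spawn(3))
    n = config.n_blood
    probs = literal_probs or {}
    # every configured marker gets a planted pass-pattern; markers outside the
    # gate act as decoys that fire on a random cell subset, so gates that
    # include them are genuinely worse, not near-duplicates
    gate_genes = {l.gene for l in lits}
    all_lits = list(lits) + [
        Literal(m.gene, "low") for m in config.markers if m.gene not in gate_genes
    ]
    states = {lit: rng_state.random(n) < probs.get(lit.gene, 0.5) for lit in all_lits}
    truth_label = gate.evaluate(states)
    labels = truth_label ^ (rng_noise.random(n) < label_noise)

    genes = [m.gene for m in config.markers] + [
        f"G{i:04d}" for i in range(config.n_genes - len(config.markers))
    ]
    base_mean = rng_counts.lognormal(config.nb_mean_log_mu, config.nb_mean_log_sd,
                                     config.n_genes)
    for mi, spec in enumerate(config.markers):
        if spec.base_mean is not None:
            base_mean[mi] = spec.base_mean
    counts = _nb_counts(
        rng_counts, np.tile(base_mean[:, None], (1, n)), config.nb_dispersion
    ).astype(np.int64)
    gene_row = {g: i for i, g in enumerate(genes)}
    for lit in all_lits:
        on = states[lit]  # literal passes
        expressed = 1 + rng_counts.poisson(1.5, n)
        row = gene_row[lit.gene]
        if lit.direction == "low":
            counts[row] = np.where(on, 0, expressed)
        else:
            counts[row] = np.where(on, expressed, 0)

    meta = pd.DataFrame(
        {"sample_id": "PLANT", "patient_id": "P1", "compartment": "blood"},
        index=pd.Index([f"B{i:05d}" for i in range(n)], name="barcode"),
    )
    bundle = SampleBundle(
        sample_id="PLANT", species="human", counts=counts,
        gene_ids=np.asarray(genes, dtype=object), cell_meta=meta,
    )
    return bundle, np.asarray(labels, dtype=bool), gate


def write_outputs(sim: SimulatedSample, out_dir) -> dict:
    """Write the standard input dialects: MTX/TSVs, contig CSV, truth JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = write_sample(sim.bundle, out)
    contigs = out / "filtered_contig_annotations.csv"
    sim.chains.to_csv(contigs, index=False)
    truth_path = out / "ground_truth.json"
    truth_path.write_text(sim.truth.to_json())
    paths["contigs"] = str(contigs)
    paths["truth"] = str(truth_path)
    return paths
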