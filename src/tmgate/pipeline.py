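"""Pipeline orchestration: stages, manifests, and the end-to-end run.

Each stage is a pure function of (inputs, parameters, seed) that reads the
previous stage's files from a working directory, writes its own TSV/JSON
outputs, and records itself in ``manifest.json`` (with content hashes) so
stage ordering can be validated and runs reproduced. The consolidated
report collects TM fractions, top-ranked markers, pareto-optimal gates and
the best gate with its bootstrap CI and permutation p-value.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from . import gates as gates_mod
from . import io as io_mod
from . import markers as markers_mod
from . import resampling as resampling_mod
from . import simulate as simulate_mod
from . import tcr as tcr_mod
from .errors import ConfigError, InputError, TmgateError
from .xlmhg import XlmhgParams

logger = logging.getLogger(__name__)

__all__ = [
    "StageError",
    "run_pipeline",
    "stage_simulate",
    "stage_match",
    "stage_markers",
    "stage_gates",
    "stage_resample",
    "stage_report",
]

STAGE_ORDER = ["simulate", "match", "markers", "gates", "resample", "report"]


class StageError(TmgateError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage {stage!r} failed: {message}")


def _manifest_path(d: Path) -> Path:
    return d / "manifest.json"


def _load_manifest(d: Path) -> dict:
    p = _manifest_path(d)
    if p.exists():
        return json.loads(p.read_text())
    return {"stages": {}}


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _record_stage(d: Path, stage: str, outputs: Mapping[str, str]) -> None:
    man = _load_manifest(d)
    man["stages"][stage] = {
        "outputs": {k: {"path": v, "sha256": _sha256(Path(v))} for k, v in outputs.items()},
    }
    _manifest_path(d).write_text(json.dumps(man, indent=2, sort_keys=True))


def _require_stage(d: Path, stage: str, needed_by: str) -> dict:
    man = _load_manifest(d)
    if stage not in man["stages"]:
        raise StageError(needed_by, f"required stage {stage!r} has not been run in {d}")
    return man["stages"][stage]


def stage_simulate(work_dir, sim_config: Optional[simulate_mod.SimConfig] = None,
                   seed: Optional[int] = None) -> dict:
    """Generate a synthetic paired sample and write its input files."""
    from dataclasses import replace

    d = Path(work_dir)
    cfg = sim_config or simulate_mod.SimConfig()
    if seed is not None:
        cfg = replace(cfg, rng_seed=int(seed))
    sim = simulate_mod.simulate_paired_sample(cfg)
    paths = simulate_mod.write_outputs(sim, d)
    _record_stage(d, "simulate", paths)
    return paths


def _load_bundle_and_chains(d: Path, stage: str) -> tuple[io_mod.SampleBundle, pd.DataFrame]:
    try:
        bundle = io_mod.load_sample(
            d / "matrix.mtx", d / "features.tsv", d / "barcodes.tsv",
            d / "cell_meta.tsv", sample_id=d.name or "sample",
            min_features=0, min_cells_per_gene=0,
        )
        contigs = d / "filtered_contig_annotations.csv"
        if not contigs.exists():
            raise InputError(f"missing contig CSV {contigs}")
        chains = tcr_mod.read_contigs(contigs)
    except TmgateError as exc:
        raise StageError(stage, str(exc)) from exc
    return bundle, chains


def stage_match(work_dir) -> dict:
    """Assign clonotypes and TM / blood-matching labels; write label tables."""
    d = Path(work_dir)
    bundle, chains = _load_bundle_and_chains(d, "match")
    clones = tcr_mod.assign_clonotypes(chains)
    comp = bundle.cell_meta["compartment"]
    blood = {bc: clones.get(bc) for bc in comp.index[comp == "blood"]}
    tumor = {bc: clones.get(bc) for bc in comp.index[comp == "tumor"]}
    labels = tcr_mod.label_matching(blood, tumor)
    labels_path = d / "cell_labels.tsv"
    out = labels.copy()
    out["clone_key"] = out["clone_key"].map(lambda k: "" if k is None else repr(k))
    out.reset_index().to_csv(labels_path, sep="\t", index=False)

    sizes_b, _ = tcr_mod.clone_size_table(blood, "blood")
    sizes_t, _ = tcr_mod.clone_size_table(tumor, "tumor")
    sizes = pd.concat([sizes_b, sizes_t], ignore_index=True)
    sizes["clone_key"] = sizes["clone_key"].map(repr)
    clone_path = d / "clone_table.tsv"
    sizes.to_csv(clone_path, sep="\t", index=False)
    _record_stage(d, "match", {"cell_labels": str(labels_path), "clone_table": str(clone_path)})
    return {"cell_labels": str(labels_path), "clone_table": str(clone_path)}


def _blood_tm_mask(d: Path, bundle: io_mod.SampleBundle, stage: str) -> tuple[np.ndarray, np.ndarray]:
    """(cell mask of paired-chain blood cells, TM labels over that mask)."""
    _require_stage(d, "match", stage)
    lab = pd.read_csv(d / "cell_labels.tsv", sep="\t").set_index("barcode")
    lab = lab.reindex(bundle.barcodes)
    is_blood = lab["compartment"] == "blood"
    paired = lab["label"].isin([tcr_mod.TM, tcr_mod.NON_TM])
    mask = (is_blood & paired).to_numpy()
    tm = (lab["label"] == tcr_mod.TM).to_numpy()[mask]
    return mask, tm


def stage_markers(work_dir, x_frac: float = 0.15) -> dict:
    """XL-mHG + grid-AUC scan over all genes on paired-chain blood cells."""
    d = Path(work_dir)
    bundle, _ = _load_bundle_and_chains(d, "markers")
    mask, tm = _blood_tm_mask(d, bundle, "markers")
    if tm.sum() == 0 or tm.all():
        raise StageError("markers", "need both TM and non-TM blood cells")
    sub = bundle.subset_cells(mask)
    try:
        table = markers_mod.marker_scan(
            sub.counts, list(sub.gene_ids), tm, XlmhgParams(x_frac=x_frac)
        )
    except TmgateError as exc:
        raise StageError("markers", str(exc)) from exc
    path = d / "markers.tsv"
    table.to_csv(path, sep="\t", index=False)
    _record_stage(d, "markers", {"markers": str(path)})
    return {"markers": str(path)}


def _literals_from_markers(table: pd.DataFrame, n_top: int) -> list[gates_mod.Literal]:
    ranked = table.sort_values(["q", "p"]).drop_duplicates("gene").head(n_top)
    lits = []
    for row in ranked.itertuples():
        direction = "low" if row.direction == "marker_negation" else "high"
        lits.append(gates_mod.Literal(row.gene, direction))
    return lits


def stage_gates(work_dir, literals: Optional[Sequence[str]] = None, n_top: int = 4,
                universal_threshold: float = 0.001) -> dict:
    """Enumerate and evaluate all gates over the chosen marker literals."""
    d = Path(work_dir)
    bundle, _ = _load_bundle_and_chains(d, "gates")
    mask, tm = _blood_tm_mask(d, bundle, "gates")
    if literals:
        lits = [gates_mod.parse_gate(s).literal for s in literals]
    else:
        _require_stage(d, "markers", "gates")
        table = pd.read_csv(d / "markers.tsv", sep="\t")
        lits = _literals_from_markers(table, n_top)
    sub = bundle.subset_cells(mask)
    expr = pd.DataFrame(sub.counts.T, columns=sub.gene_ids)
    params = gates_mod.GateEvalParams(universal_threshold=universal_threshold)
    try:
        all_gates = gates_mod.enumerate_gates(lits)
        evals = [gates_mod.evaluate_gate(g, expr, tm, params) for g in all_gates]
    except (TmgateError, KeyError) as exc:
        raise StageError("gates", str(exc)) from exc
    gates_mod.pareto_filter(evals)
    frame = gates_mod.evaluations_frame(evals).sort_values("penalty")
    path = d / "gates.tsv"
    frame.to_csv(path, sep="\t", index=False)
    _record_stage(d, "gates", {"gates": str(path)})
    return {"gates": str(path)}


def stage_resample(work_dir, gate: Optional[str] = None, B: int = 1000,
                   seed: int = 0, universal_threshold: float = 0.001) -> dict:
    """Bootstrap CI and permutation p for the (best) gate's performance."""
    d = Path(work_dir)
    bundle, _ = _load_bundle_and_chains(d, "resample")
    mask, tm = _blood_tm_mask(d, bundle, "resample")
    if gate is None:
        _require_stage(d, "gates", "resample")
        frame = pd.read_csv(d / "gates.tsv", sep="\t")
        gate = frame.sort_values("penalty").iloc[0]["gate"]
    expr_all = pd.DataFrame(bundle.subset_cells(mask).counts.T,
                            columns=bundle.gene_ids)
    g = gates_mod.parse_gate(gate)
    params = gates_mod.GateEvalParams(universal_threshold=universal_threshold)
    out = {"gate": str(g), "B": B, "seed": seed}
    try:
        for stat_name in ("sensitivity", "specificity"):
            def stat(df, labels, _n=stat_name):
                ev = gates_mod.evaluate_gate(g, df, labels, params)
                return getattr(ev, _n)
            rp = resampling_mod.ResamplingParams(B=B, rng_seed=seed)
            ci = resampling_mod.bootstrap_ci(expr_all, tm, stat, rp, name=stat_name)
            pp = resampling_mod.permutation_p(expr_all, tm, stat, rp, name=stat_name)
            out[stat_name] = {
                "point": ci.point, "ci_lo": ci.ci_lo, "ci_hi": ci.ci_hi,
                "empirical_p": pp.p_display(), "B": B,
            }
    except TmgateError as exc:
        raise StageError("resample", str(exc)) from exc
    path = d / "resampling.json"
    path.write_text(json.dumps(out, indent=2, sort_keys=True))
    _record_stage(d, "resample", {"resampling": str(path)})
    return {"resampling": str(path)}


def stage_report(work_dir) -> dict:
    """Consolidate stage outputs into report.json; fails on missing stages."""
    d = Path(work_dir)
    for needed in ("match", "markers", "gates"):
        _require_stage(d, needed, "report")
    labels = pd.read_csv(d / "cell_labels.tsv", sep="\t")
    blood = labels[labels["compartment"] == "blood"]
    paired = blood[blood["label"].isin([tcr_mod.TM, tcr_mod.NON_TM])]
    markers = pd.read_csv(d / "markers.tsv", sep="\t")
    gates_frame = pd.read_csv(d / "gates.tsv", sep="\t").sort_values("penalty")
    report = {
        "n_blood_cells": int(len(blood)),
        "n_paired_chain_blood_cells": int(len(paired)),
        "tm_fraction": float((paired["label"] == tcr_mod.TM).mean()) if len(paired) else None,
        "top_markers": markers.sort_values("q").head(10).to_dict(orient="records"),
        "pareto_gates": gates_frame[gates_frame["pareto"] == True].to_dict(orient="records"),  # noqa: E712
        "best_gate": gates_frame.iloc[0].to_dict(),
    }
    res_path = d / "resampling.json"
    if res_path.exists():
        report["best_gate_uncertainty"] = json.loads(res_path.read_text())
    path = d / "report.json"
    path.write_text(json.dumps(report, indent=2, sort_keys=True, default=str))
    _record_stage(d, "report", {"report": str(path)})
    return {"report": str(path)}


def run_pipeline(config: Mapping) -> dict:
    """End-to-end multi-sample run from a configuration mapping.

    Configuration keys: ``seed``, ``out_dir``, ``samples`` (list of
    {id, patient, simulate: {...}} or {id, patient, paths: {...}}), and
    optional ``markers`` / ``consensus`` / ``gates`` / ``resampling``
    parameter blocks. Returns the consolidated report dictionary (also
    written to out_dir/report.json).
    """
    if "out_dir" not in config or "samples" not in config:
        raise ConfigError("config needs 'out_dir' and 'samples'")
    out_dir = Path(config["out_dir"])
    out_dir.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    mk_cfg = dict(config.get("markers", {}))
    cons_cfg = dict(config.get("consensus", {}))
    gate_cfg = dict(config.get("gates", {}))
    res_cfg = dict(config.get("resampling", {}))

    sample_tables: dict[str, pd.DataFrame] = {}
    pooled_expr: list[pd.DataFrame] = []
    pooled_tm: list[np.ndarray] = []
    per_sample_report = {}
    for i, spec in enumerate(config["samples"]):
        sid = spec.get("id", f"S{i+1}")
        sdir = out_dir / sid
        sdir.mkdir(exist_ok=True)
        if "simulate" in spec:
            sim_kwargs = dict(spec["simulate"])
            sim_kwargs.setdefault("rng_seed", (seed * 1000 + i) % (2**31 - 1))
            stage_simulate(sdir, simulate_mod.SimConfig(**sim_kwargs))
        elif "paths" in spec:
            _stage_ingest(sdir, spec["paths"])
        else:
            raise ConfigError(f"sample {sid}: needs 'simulate' or 'paths'")
        stage_match(sdir)
        stage_markers(sdir, x_frac=mk_cfg.get("x_frac", 0.15))
        table = pd.read_csv(sdir / "markers.tsv", sep="\t")
        sample_tables[sid] = table

        bundle, _ = _load_bundle_and_chains(sdir, "gates")
        mask, tm = _blood_tm_mask(sdir, bundle, "gates")
        sub = bundle.subset_cells(mask)
        pooled_expr.append(pd.DataFrame(sub.counts.T, columns=sub.gene_ids))
        pooled_tm.append(tm)
        labels = pd.read_csv(sdir / "cell_labels.tsv", sep="\t")
        blood = labels[labels["compartment"] == "blood"]
        paired = blood[blood["label"].isin([tcr_mod.TM, tcr_mod.NON_TM])]
        per_sample_report[sid] = {
            "tm_fraction": float((paired["label"] == tcr_mod.TM).mean()) if len(paired) else None,
            "n_paired_chain_blood_cells": int(len(paired)),
        }

    # consensus marker ranking across samples
    if len(sample_tables) >= 2:
        cons = markers_mod.consensus_rank(
            sample_tables,
            markers_mod.ConsensusParams(
                q_cut=cons_cfg.get("q_cut", 0.05),
                min_samples=cons_cfg.get("min_samples", min(4, len(sample_tables))),
                exclusion_list=tuple(cons_cfg.get("exclusion_list",
                                                  ("CD8A", "CCL4", "CCL5", "MIF"))),
            ),
        )
    else:
        only = next(iter(sample_tables.values()))
        cons = only.sort_values("q").copy()
        cons["mean_auc"] = cons["auc"]
    cons.to_csv(out_dir / "consensus_markers.tsv", sep="\t", index=False)

    expr = pd.concat(pooled_expr, ignore_index=True, join="inner")
    tm = np.concatenate(pooled_tm)
    n_top = int(gate_cfg.get("n_top", 4))
    top = cons.drop_duplicates("gene").head(n_top)
    lits = [
        gates_mod.Literal(row.gene, "low" if row.direction == "marker_negation" else "high")
        for row in top.itertuples()
    ]
    if not lits:
        raise StageError("gates", "no consensus markers available to build gates from")
    gparams = gates_mod.GateEvalParams(
        universal_threshold=gate_cfg.get("universal_threshold", 0.001)
    )
    all_gates = gates_mod.enumerate_gates(lits)
    evals = [gates_mod.evaluate_gate(g, expr, tm, gparams) for g in all_gates]
    gates_mod.pareto_filter(evals)
    frame = gates_mod.evaluations_frame(evals).sort_values("penalty")
    frame.to_csv(out_dir / "gates.tsv", sep="\t", index=False)
    best = gates_mod.select_best_gate(evals)

    B = int(res_cfg.get("B", 1000))
    rp = resampling_mod.ResamplingParams(B=B, rng_seed=seed)
    uncertainty = {}
    for stat_name in ("sensitivity", "specificity"):
        def stat(df, labels, _n=stat_name):
            return getattr(gates_mod.evaluate_gate(best.gate, df, labels, gparams), _n)
        ci = resampling_mod.bootstrap_ci(expr, tm, stat, rp, name=stat_name)
        pp = resampling_mod.permutation_p(expr, tm, stat, rp, name=stat_name)
        uncertainty[stat_name] = {
            "point": ci.point, "ci_lo": ci.ci_lo, "ci_hi": ci.ci_hi,
            "empirical_p": pp.p_display(), "B": B,
        }

    report = {
        "seed": seed,
        "samples": per_sample_report,
        "consensus_top": cons.head(10).to_dict(orient="records"),
        "best_gate": {
            "gate": str(best.gate),
            "sensitivity": best.sensitivity,
            "specificity": best.specificity,
            "penalty": best.penalty,
        },
        "n_gates_evaluated": len(evals),
        "n_pareto_gates": int(sum(e.pareto for e in evals)),
        "best_gate_uncertainty": uncertainty,
    }
    (out_dir / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    return report


def _stage_ingest(sdir: Path, paths: Mapping[str, str]) -> None:
    """Copy externally supplied sample files into the working directory."""
    import shutil

    mapping = {
        "counts": "matrix.mtx", "features": "features.tsv",
        "barcodes": "barcodes.tsv", "meta": "cell_meta.tsv",
        "contigs": "filtered_contig_annotations.csv",
    }
    outputs = {}
    for key, fname in mapping.items():
        if key not in paths:
            raise StageError("ingest", f"missing path for {key!r}")
        src = Path(paths[key])
        if not src.exists():
            raise StageError("ingest", f"file not found: {src}")
        shutil.copy(src, sdir / fname)
        outputs[key] = str(sdir / fname)
    _record_stage(sdir, "simulate", outputs)  # fulfils the input-stage slot
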