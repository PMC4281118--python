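"""End-to-end orchestration: simulate → deplete → DE (both platforms) → merge
→ enrichment → cytometry → dose–response, as plain files on disk.

Stages run in dependency order; each stage writes its outputs before the
next starts, and a stage is skipped when all of its outputs already exist
(so deleting downstream files re-runs only downstream stages).  The run
manifest records the config hash, the seed, and a SHA-256 digest per output
file; deterministic stages reproduce byte-identical CSVs for the same
config and seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Callable, Dict, List

import numpy as np
import pandas as pd
import yaml

from . import __version__
from ._rng import spawn
from .config import load_config, validate_config
from .cytometry import compensate, estimate_spillover, fit_4pl, gate, normalize_scale
from .de import (
    compute_rpkm,
    estimate_size_factors,
    filter_expressed_rpkm,
    moderated_t,
    nbinom_exact_test,
    normalize_counts,
    preprocess_array,
)
from .integrate import merge_platforms, overlap_enrichment, rank_table
from .population import DepletionSpec, PopulationConfig, apply_depletion, make_population
from .simulate import (
    SpilloverMatrix,
    make_gene_annotation,
    make_gene_profiles,
    simulate_array_experiment,
    simulate_counts_experiment,
    simulate_dose_response,
    simulate_single_cell_table,
)
from .containers import CountMatrix, ExpressionMatrix

__all__ = ["RunManifest", "run_pipeline", "PipelineError"]

log = logging.getLogger("subelim")


class PipelineError(RuntimeError):
    pass


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _config_hash(cfg: Dict[str, Any]) -> str:
    canonical = yaml.safe_dump(cfg, sort_keys=True).encode()
    return hashlib.sha256(canonical).hexdigest()


@dataclass
class RunManifest:
    config_hash: str
    seed: int
    version: str
    stages: Dict[str, Dict[str, str]] = field(default_factory=dict)
    skipped: List[str] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(
            {
                "config_hash": self.config_hash,
                "seed": self.seed,
                "version": self.version,
                "stages": self.stages,
                "skipped": self.skipped,
            },
            indent=2,
            sort_keys=True,
        )


def _depletion_spec(cfg: Dict[str, Any]) -> DepletionSpec:
    dep = cfg["depletion"]
    if dep["agonist"] == "control":
        return DepletionSpec.control()
    if dep["agonist"] == "capsaicin":
        return DepletionSpec.capsaicin(dose_nm=dep["dose_nm"], duration_min=dep["duration_min"])
    return DepletionSpec.rtx(dose_nm=dep["dose_nm"], duration_min=dep["duration_min"])


def _spillover(cfg: Dict[str, Any]) -> SpilloverMatrix:
    spill = cfg["spill"]
    pairs = {}
    for key, slope in spill["pairs"].items():
        receiver, source = key.split("<-")
        pairs[(receiver, source)] = slope
    return SpilloverMatrix.from_pairs(spill["channels"], pairs)


def run_pipeline(config, seed: int, out_dir) -> RunManifest:
    """Execute the full pipeline; returns the reproducibility manifest."""
    if isinstance(config, (str, Path)):
        cfg = load_config(config)
    else:
        validate_config(config)
        cfg = config
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config_hash=_config_hash(cfg), seed=int(seed), version=__version__)

    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(logging.Formatter("[subelim:%(stage)s] %(message)s"))
    if not log.handlers:
        log.addHandler(handler)
        log.setLevel(logging.INFO)

    state: Dict[str, Any] = {"cfg": cfg, "seed": int(seed), "out": out}
    stages: List[tuple[str, Callable, List[str]]] = [
        ("population", _stage_population, ["cells.csv", "gene_profiles.csv", "truth.csv"]),
        ("bulk_array", _stage_bulk_array, ["array_expression.csv", "array_detection.csv"]),
        ("array_de", _stage_array_de, ["array_stats.csv", "array_meta.json"]),
        ("bulk_counts", _stage_bulk_counts, ["counts.csv", "gene_annotation.tsv"]),
        ("seq_de", _stage_seq_de, ["seq_stats.csv", "seq_meta.json"]),
        ("merge", _stage_merge, ["merged.csv", "report_table.csv", "enrichment.json"]),
        ("cytometry", _stage_cytometry, ["cells_table.csv", "gate_summary.json"]),
        ("doseresponse", _stage_doseresponse, ["doseresponse.csv", "doseresponse_fit.json"]),
    ]
    for name, fn, outputs in stages:
        paths = [out / p for p in outputs]
        extra = {"stage": name}
        if all(p.exists() for p in paths):
            log.info("outputs exist — skipped", extra=extra)
            manifest.skipped.append(name)
        else:
            log.info("running", extra=extra)
            try:
                fn(state)
            except Exception as exc:  # noqa: BLE001 — name the failing stage
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
            missing = [str(p) for p in paths if not p.exists()]
            if missing:
                raise PipelineError(f"stage {name!r} did not write {missing}")
        manifest.stages[name] = {p.name: _sha256(p) for p in paths}
    (out / "manifest.json").write_text(manifest.to_json())
    return manifest


# ---------------------------------------------------------------- stages


def _stage_population(state: Dict[str, Any]) -> None:
    cfg, seed, out = state["cfg"], state["seed"], state["out"]
    pop_cfg = PopulationConfig.from_neurons(
        cfg["population"]["n_neurons"],
        f_trpv1_pos=cfg["population"]["f_trpv1_pos"],
        f_nf200=cfg["population"]["f_nf200"],
        neuron_share=cfg["population"]["neuron_share"],
    )
    profiles, truth = make_gene_profiles(
        cfg["genes"]["n_genes"], cfg["genes"]["n_enriched"], seed=spawn(seed, "genes").integers(2**31)
    )
    pop = make_population(pop_cfg, seed=spawn(seed, "pop").integers(2**31), gene_profiles=profiles)
    pop.cells.to_csv(out / "cells.csv", index=False)
    profiles.rename_axis("gene").to_csv(out / "gene_profiles.csv")
    truth.rename_axis("gene").to_csv(out / "truth.csv")
    state["pop"] = pop


def _require_population(state: Dict[str, Any]):
    if "pop" not in state:
        out = state["out"]
        for name in ("cells.csv", "gene_profiles.csv"):
            if not (out / name).exists():
                raise PipelineError(f"missing upstream file {out / name}")
        from .population import CellPopulation

        cells = pd.read_csv(out / "cells.csv")
        profiles = pd.read_csv(out / "gene_profiles.csv", index_col="gene")
        state["pop"] = CellPopulation(cells=cells, gene_profiles=profiles)
    return state["pop"]


def _stage_bulk_array(state: Dict[str, Any]) -> None:
    cfg, seed, out = state["cfg"], state["seed"], state["out"]
    pop = _require_population(state)
    expr = simulate_array_experiment(
        pop,
        _depletion_spec(cfg),
        cfg["array"]["n_control"],
        cfg["array"]["n_depleted"],
        cfg["array"]["noise_sd_log2"],
        seed=spawn(seed, "bulk_array").integers(2**31),
        background_mean=cfg["array"]["background_mean"],
        background_sd=cfg["array"]["background_sd"],
    )
    expr.values.rename_axis("gene").to_csv(out / "array_expression.csv")
    expr.detection_p.rename_axis("gene").to_csv(out / "array_detection.csv")
    state["array_expr"] = expr


def _load_array(state: Dict[str, Any]) -> ExpressionMatrix:
    if "array_expr" not in state:
        out = state["out"]
        values = pd.read_csv(out / "array_expression.csv", index_col="gene")
        det = pd.read_csv(out / "array_detection.csv", index_col="gene")
        conditions = pd.Series(
            ["control" if c.startswith("control") else "depleted" for c in values.columns],
            index=values.columns,
        )
        state["array_expr"] = ExpressionMatrix(values, det, conditions)
    return state["array_expr"]


def _stage_array_de(state: Dict[str, Any]) -> None:
    cfg, out = state["cfg"], state["out"]
    expr = _load_array(state)
    filtered, report = preprocess_array(expr, cfg["thresholds"]["detection_alpha"])
    result = moderated_t(filtered)
    result.table.to_csv(out / "array_stats.csv")
    meta = {
        "n_probes_total": report.n_total,
        "n_probes_detected": report.n_kept,
        "percent_of_array": report.percent_of_array,
        "d0": None if np.isinf(result.d0) else result.d0,
        "s0_sq": result.s0_sq,
        "detection_alpha": report.detection_alpha,
    }
    (out / "array_meta.json").write_text(json.dumps(meta, indent=2))
    state["array_stats"] = result.table


def _stage_bulk_counts(state: Dict[str, Any]) -> None:
    cfg, seed, out = state["cfg"], state["seed"], state["out"]
    pop = _require_population(state)
    annotation = make_gene_annotation(
        list(pop.gene_profiles.index), seed=spawn(seed, "annot").integers(2**31)
    )
    cm = simulate_counts_experiment(
        pop,
        _depletion_spec(cfg),
        cfg["seq"]["n_control"],
        cfg["seq"]["n_depleted"],
        cfg["seq"]["depth"],
        cfg["seq"]["dispersion"],
        annotation,
        seed=spawn(seed, "bulk_counts").integers(2**31),
    )
    cm.counts.rename_axis("gene").to_csv(out / "counts.csv")
    annotation.to_csv(out / "gene_annotation.tsv", sep="\t")
    state["count_matrix"] = cm


def _load_counts(state: Dict[str, Any]) -> CountMatrix:
    if "count_matrix" not in state:
        out = state["out"]
        counts = pd.read_csv(out / "counts.csv", index_col="gene")
        ann = pd.read_csv(out / "gene_annotation.tsv", sep="\t", index_col="gene_id")
        conditions = pd.Series(
            ["control" if c.startswith("control") else "depleted" for c in counts.columns],
            index=counts.columns,
        )
        state["count_matrix"] = CountMatrix(
            counts=counts, lengths=ann["length_bp"], gc=ann["gc_fraction"], conditions=conditions
        )
    return state["count_matrix"]


def _stage_seq_de(state: Dict[str, Any]) -> None:
    cfg, out = state["cfg"], state["out"]
    cm = _load_counts(state)
    rpkm_raw = compute_rpkm(cm.counts, cm.lengths)
    normalized = normalize_counts(cm)
    size_factors = estimate_size_factors(normalized.counts)
    result = nbinom_exact_test(normalized, size_factors=size_factors)
    keep = filter_expressed_rpkm(rpkm_raw, cfg["thresholds"]["min_rpkm_detect"])
    table = result.table.loc[result.table.index.intersection(keep)].copy()
    table["rpkm"] = rpkm_raw.mean(axis=1).loc[table.index]
    table = table.rename_axis("gene")
    table.to_csv(out / "seq_stats.csv")
    meta = {
        "n_genes_total": int(len(cm.genes)),
        "n_genes_expressed": int(len(keep)),
        "size_factors": {k: float(v) for k, v in size_factors.items()},
        "min_rpkm": cfg["thresholds"]["min_rpkm_detect"],
    }
    (out / "seq_meta.json").write_text(json.dumps(meta, indent=2))
    state["seq_stats"] = table


def _stage_merge(state: Dict[str, Any]) -> None:
    cfg, out = state["cfg"], state["out"]
    if "array_stats" not in state:
        state["array_stats"] = pd.read_csv(out / "array_stats.csv", index_col="probe")
    if "seq_stats" not in state:
        state["seq_stats"] = pd.read_csv(out / "seq_stats.csv", index_col="gene")
    merged = merge_platforms(
        state["array_stats"],
        state["seq_stats"],
        p_cut=cfg["thresholds"]["adj_p"],
        fc_cut=cfg["thresholds"]["fold_change"],
    )
    merged.table.rename_axis("gene").to_csv(out / "merged.csv")
    report = rank_table(merged, min_rpkm=cfg["thresholds"]["min_rpkm_table"])
    report.rename_axis("gene").to_csv(out / "report_table.csv")
    truth_path = out / "truth.csv"
    enrichment = {}
    if truth_path.exists():
        truth = pd.read_csv(truth_path, index_col="gene")
        reference = truth.index[truth["enriched"]]
        res = overlap_enrichment(
            merged.candidates("up_in_subgroup").index,
            reference,
            universe_size=cfg["thresholds"]["universe"],
        )
        enrichment = {
            "overlap": res.overlap,
            "candidate_size": res.candidate_size,
            "reference_size": res.reference_size,
            "universe": res.universe,
            "expected_overlap": res.expected_overlap,
            "p_value": res.p_value,
        }
    enrichment["n_up"] = merged.n_up
    enrichment["n_down"] = merged.n_down
    enrichment["n_discordant"] = merged.n_discordant
    (out / "enrichment.json").write_text(json.dumps(enrichment, indent=2))


def _stage_cytometry(state: Dict[str, Any]) -> None:
    cfg, seed, out = state["cfg"], state["seed"], state["out"]
    pop = _require_population(state)
    spill = _spillover(cfg)
    depleted = apply_depletion(
        pop, _depletion_spec(cfg), seed=spawn(seed, "cyto_dep").integers(2**31)
    )
    table_c, controls = simulate_single_cell_table(
        pop, cfg["panel"], spill, seed=spawn(seed, "cyto").integers(2**31), condition="control"
    )
    table_t, _ = simulate_single_cell_table(
        depleted, cfg["panel"], spill, seed=spawn(seed, "cyto_t").integers(2**31),
        condition="treated"
    )
    table = pd.concat([table_c, table_t], ignore_index=True)
    est = estimate_spillover(controls, channels=spill.channels)
    table = compensate(table, est)
    table = normalize_scale(
        table, "control", channels=spill.channels,
        scale_constant=cfg["gating"]["scale_constant"]
    )
    table.to_csv(out / "cells_table.csv", index=False)
    channel = cfg["gating"]["channel"]
    summary = {}
    for condition in ("control", "treated"):
        values = table.loc[table["condition"] == condition, f"scaled_{channel}"]
        g = gate(values, method="fixed", fixed_threshold=cfg["gating"]["fixed_threshold"])
        summary[condition] = {
            "threshold": g.threshold,
            "n": g.n,
            "n_positive": g.n_positive,
            "percent_positive": g.percent_positive,
            "ci_low": g.ci_low,
            "ci_high": g.ci_high,
        }
    (out / "gate_summary.json").write_text(json.dumps(summary, indent=2))


def _stage_doseresponse(state: Dict[str, Any]) -> None:
    cfg, seed, out = state["cfg"], state["seed"], state["out"]
    dr = cfg["doseresponse"]
    data = simulate_dose_response(
        dr["doses_nm"],
        dr["n_per_dose"],
        dr["cv"],
        seed=spawn(seed, "doseresponse").integers(2**31),
        bottom=dr["bottom"],
        top=dr["top"],
        ec50=dr["ec50_nm"],
        hill=dr["hill"],
    )
    data.to_csv(out / "doseresponse.csv", index=False)
    fit = fit_4pl(data["dose"], data["response"])
    payload = {**fit.params(), "bse": fit.bse, "converged": fit.converged, "ssr": fit.ssr}
    (out / "doseresponse_fit.json").write_text(json.dumps(payload, indent=2))
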