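"""Structured YAML configuration for the end-to-end pipeline.

A single document holds the population mixture, the depletion operating
points, both bulk platforms, the imaging panel and spill-over, the gating
setup, and the analysis thresholds (detection α, adjusted-p and fold-change
cuts, RPKM filters, enrichment universe) in one ``thresholds`` block.
"""

from __future__ import annotations

import copy
from pathlib import Path
from typing import Any, Dict

import yaml

__all__ = ["ConfigError", "default_config", "load_config", "validate_config", "dump_config"]


class ConfigError(ValueError):
    """Configuration schema violation; the message carries the YAML path."""


def default_config() -> Dict[str, Any]:
    return {
        "population": {
            "n_neurons": 4000,
            "f_trpv1_pos": 0.44,
            "f_nf200": 0.20,
            "neuron_share": 0.35,
        },
        "depletion": {
            "agonist": "rtx",
            "dose_nm": 100.0,
            "duration_min": 30.0,
        },
        "genes": {
            "n_genes": 2000,
            "n_enriched": 100,
        },
        "array": {
            "n_control": 4,
            "n_depleted": 4,
            "noise_sd_log2": 0.15,
            "background_mean": 100.0,
            "background_sd": 30.0,
        },
        "seq": {
            "n_control": 3,
            "n_depleted": 3,
            "depth": 1_000_000,
            "dispersion": 0.05,
        },
        "panel": {"ch1": "UCHL1", "ch2": "TRPV1", "ch3": "CART"},
        "spill": {
            "channels": ["ch1", "ch2", "ch3"],
            "pairs": {"ch2<-ch1": 0.04, "ch3<-ch2": 0.06, "ch1<-ch2": 0.02},
        },
        "gating": {
            "fixed_threshold": 0.49,
            "scale_constant": 1,
            "channel": "ch2",
        },
        "doseresponse": {
            "bottom": 1.0,
            "top": 3.0,
            "ec50_nm": 377.0,
            "hill": 1.5,
            "doses_nm": [1.0, 5.18, 26.8, 139.0, 720.0, 3728.0, 19307.0, 100000.0],
            "n_per_dose": 3,
            "cv": 0.1,
        },
        "thresholds": {
            "detection_alpha": 0.01,
            "adj_p": 0.05,
            "fold_change": 1.5,
            "min_rpkm_detect": 0.1,
            "min_rpkm_table": 0.5,
            "universe": 22_777,
        },
    }


def _check(cond: bool, path: str, message: str) -> None:
    if not cond:
        raise ConfigError(f"{path}: {message}")


def validate_config(cfg: Dict[str, Any]) -> None:
    _check(isinstance(cfg, dict), "<root>", "config must be a mapping")
    for section in default_config():
        _check(section in cfg, section, "missing section")
    pop = cfg["population"]
    _check(pop["n_neurons"] > 0, "population.n_neurons", "must be positive")
    for key in ("f_trpv1_pos", "f_nf200", "neuron_share"):
        _check(0 <= pop[key] <= 1, f"population.{key}", "must lie in [0, 1]")
    _check(
        pop["f_trpv1_pos"] + pop["f_nf200"] <= 1,
        "population.f_trpv1_pos",
        "within-neuron fractions exceed 1",
    )
    dep = cfg["depletion"]
    _check(dep["agonist"] in ("capsaicin", "rtx", "control"), "depletion.agonist", "unknown agonist")
    _check(dep["dose_nm"] >= 0, "depletion.dose_nm", "must be >= 0")
    _check(cfg["genes"]["n_enriched"] <= cfg["genes"]["n_genes"], "genes.n_enriched", "exceeds n_genes")
    _check(cfg["array"]["n_control"] >= 2, "array.n_control", "need >= 2 replicates")
    _check(cfg["array"]["n_depleted"] >= 2, "array.n_depleted", "need >= 2 replicates")
    _check(cfg["seq"]["depth"] > 0, "seq.depth", "must be positive")
    _check(cfg["seq"]["dispersion"] >= 0, "seq.dispersion", "must be >= 0")
    spill = cfg["spill"]
    channels = spill["channels"]
    for pair, slope in spill["pairs"].items():
        _check("<-" in pair, f"spill.pairs.{pair}", "pair must be '<receiver><-<source>'")
        i, j = pair.split("<-")
        _check(i in channels and j in channels, f"spill.pairs.{pair}", "unknown channel")
        _check(0 <= slope < 1, f"spill.pairs.{pair}", "slope must lie in [0, 1)")
    for ch in cfg["panel"]:
        _check(ch in channels, f"panel.{ch}", "channel not in spill.channels")
    _check(cfg["gating"]["scale_constant"] in (1, 1000), "gating.scale_constant", "use 1 or 1000")
    dr = cfg["doseresponse"]
    _check(dr["bottom"] <= dr["top"], "doseresponse.bottom", "bottom must not exceed top")
    _check(dr["ec50_nm"] > 0, "doseresponse.ec50_nm", "must be positive")
    doses = dr["doses_nm"]
    _check(len(doses) >= 4, "doseresponse.doses_nm", "need >= 4 doses")
    _check(all(d > 0 for d in doses), "doseresponse.doses_nm", "doses must be positive")
    _check(
        all(b > a for a, b in zip(doses, doses[1:])),
        "doseresponse.doses_nm",
        "doses must be strictly increasing",
    )
    th = cfg["thresholds"]
    for key in ("detection_alpha", "adj_p"):
        _check(0 < th[key] < 1, f"thresholds.{key}", "must lie in (0, 1)")
    _check(th["fold_change"] > 1, "thresholds.fold_change", "must exceed 1")
    _check(th["universe"] > 0, "thresholds.universe", "must be positive")


def _deep_merge(base: Dict[str, Any], override: Dict[str, Any]) -> Dict[str, Any]:
    out = copy.deepcopy(base)
    for key, value in override.items():
        if key in out and isinstance(out[key], dict) and isinstance(value, dict):
            out[key] = _deep_merge(out[key], value)
        else:
            out[key] = copy.deepcopy(value)
    return out


def load_config(path=None) -> Dict[str, Any]:
    """Load a YAML config merged over the defaults and validate it."""
    cfg = default_config()
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        if not isinstance(user, dict):
            raise ConfigError("<root>: config file must contain a mapping")
        cfg = _deep_merge(cfg, user)
    validate_config(cfg)
    return cfg


def dump_config(cfg: Dict[str, Any], path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)
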