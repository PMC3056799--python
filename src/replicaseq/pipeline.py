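"""End-to-end orchestration: filter -> differential -> replication -> GSEA
-> clustering, with a manifest capturing configuration and record counts.

The pipeline is driven by a :class:`PipelineConfig` (usually loaded from a
YAML file). Reruns with the same config and seed are byte-identical for
every output.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .errors import ConfigurationError
from .differential import CONTRASTS, differential_table, get_contrast
from .filtering import present_filter
from .gsea import gsea_campaign, results_table
from .clustering import cluster_arrays, cut_tree
from .io_formats import (
    ExpressionExperiment,
    read_annotation,
    read_experiment,
    read_gmt,
    write_results_tables,
)
from .replication import directional_intersection, onoff_calls

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Paths, thresholds and stage settings for one full run."""

    exp1_dir: str
    exp2_dir: str
    out_dir: str
    annotation: str | None = None
    gmt_paths: list = field(default_factory=list)
    conditions: list = field(default_factory=lambda: [["CONTROL"], ["ALC_NTC", "ALC_NTO"]])
    contrast: str = "CTRL_vs_ALC"
    gsea_contrasts: list = field(
        default_factory=lambda: ["CTRL_vs_ALC", "CTRL_vs_NTC", "CTRL_vs_NTO", "NTC_vs_NTO"]
    )
    alpha1: float = 0.05
    alpha2: float = 0.05
    gsea_alpha: float = 0.05
    gsea_metric: str = "signal_to_noise"
    gsea_mode: str = "gene"
    n_perm: int = 999
    cluster_metric: str = "correlation"
    seed: int | None = None

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def validate(self) -> None:
        for d in (self.exp1_dir, self.exp2_dir):
            if not Path(d).is_dir():
                raise ConfigurationError(f"experiment directory not found: {d}")
        for p in self.gmt_paths:
            if not Path(p).is_file():
                raise ConfigurationError(f"gene set file not found: {p}")
        if self.gmt_paths and self.seed is None:
            raise ConfigurationError("seed is mandatory when GSEA is enabled")

    def digest(self) -> str:
        payload = json.dumps(self.__dict__, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _load_experiment(exp_dir, platform_id) -> ExpressionExperiment:
    d = Path(exp_dir)
    return read_experiment(
        d / "signals.tsv", d / "calls.tsv", d / "samples.tsv", platform_id
    )


def run_all(config: PipelineConfig) -> dict:
    """Execute every stage and write tables plus ``manifest.json``.

    Returns the manifest dictionary. Any stage failure propagates with the
    stage name in the log context.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "config_hash": config.digest(),
        "seed": config.seed,
        "stages": {},
        "files": [],
    }

    exp1 = _load_experiment(config.exp1_dir, "platform_A")
    exp2 = _load_experiment(config.exp2_dir, "platform_B")
    annotation = read_annotation(config.annotation) if config.annotation else None
    conditions = [frozenset(c) for c in config.conditions]

    # ---- filter ----------------------------------------------------------
    log.info("stage filter")
    filt1 = present_filter(exp1, conditions)
    filt2 = present_filter(exp2, conditions)
    with open(out / "filter_report.json", "w", encoding="utf-8") as fh:
        json.dump({"exp1": filt1.to_dict(), "exp2": filt2.to_dict()}, fh, indent=1)
    manifest["files"].append("filter_report.json")
    manifest["stages"]["filter"] = {
        "exp1_retained": filt1.n_retained,
        "exp2_retained": filt2.n_retained,
    }

    # ---- differential ----------------------------------------------------
    log.info("stage differential")
    contrast = get_contrast(config.contrast)
    de1 = differential_table(exp1, contrast, alpha=config.alpha1,
                             probe_ids=filt1.retained_probe_ids)
    de2 = differential_table(exp2, contrast, alpha=config.alpha2,
                             probe_ids=filt2.retained_probe_ids)
    manifest["stages"]["differential"] = {
        "exp1_records": len(de1),
        "exp2_records": len(de2),
        "contrast": contrast.name,
    }

    # ---- replication -----------------------------------------------------
    log.info("stage replication")
    shared = sorted(
        (set(filt1.retained_probe_ids) & set(filt2.retained_probe_ids))
        & set(exp1.probe_ids)
    )
    rep = directional_intersection(de1, de2, shared, config.alpha1, config.alpha2)
    onoff = onoff_calls(exp2, contrast, de2)
    with open(out / "replication_report.json", "w", encoding="utf-8") as fh:
        json.dump(rep.to_dict(), fh, indent=1)
    manifest["files"].append("replication_report.json")
    manifest["stages"]["replication"] = {
        "n_common_tested": rep.n_common_tested,
        "n_observed": rep.n_observed,
        "onoff_calls": len(onoff),
    }

    # ---- gsea ------------------------------------------------------------
    results: dict = {
        "differential": pd.concat([de1.assign(experiment="exp1"),
                                   de2.assign(experiment="exp2")]),
        "replicated_genes": rep.shared_records,
        "onoff": onoff,
    }
    if config.gmt_paths:
        log.info("stage gsea")
        collections = [read_gmt(p) for p in config.gmt_paths]
        contrasts = [get_contrast(c) for c in config.gsea_contrasts]
        gsea_results, set_report = gsea_campaign(
            exp1, exp2, collections, contrasts,
            alpha=config.gsea_alpha, n_perm=config.n_perm, seed=config.seed,
            metric=config.gsea_metric, mode=config.gsea_mode,
            annotation=annotation,
            probe_ids1=filt1.retained_probe_ids,
            probe_ids2=filt2.retained_probe_ids,
        )
        results["gsea"] = results_table(gsea_results)
        with open(out / "gsea_report.json", "w", encoding="utf-8") as fh:
            json.dump(set_report.to_dict(), fh, indent=1)
        manifest["files"].append("gsea_report.json")
        manifest["stages"]["gsea"] = {
            "n_tests_total": set_report.n_tests_total,
            "n_shared_observed": set_report.n_shared_observed,
        }

    # ---- clustering ------------------------------------------------------
    log.info("stage clustering")
    assignments = []
    for name, exp, filt in (("exp1", exp1, filt1), ("exp2", exp2, filt2)):
        dend = cluster_arrays(exp, probe_subset=filt.retained_probe_ids,
                              metric=config.cluster_metric)
        (out / f"dendrogram_{name}.nwk").write_text(dend.to_newick() + "\n")
        manifest["files"].append(f"dendrogram_{name}.nwk")
        parts = cut_tree(dend, k=3)
        assignments.append(
            pd.DataFrame({"experiment": name, "sample_id": parts.index,
                          "cluster": parts.values})
        )
    pd.concat(assignments).to_csv(out / "cluster_assignments.tsv", sep="\t",
                                  index=False, lineterminator="\n")
    manifest["files"].append("cluster_assignments.tsv")
    manifest["stages"]["clustering"] = {"k": 3}

    written = write_results_tables(results, out)
    manifest["files"].extend(sorted(p.name for p in written.values()))

    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest
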