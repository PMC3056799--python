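"""Synthetic two-experiment microarray data with known ground truth.

The generator emulates the statistical structure the downstream analysis
assumes: two experiments on nested probe universes (platform A is a strict
subset of platform B), small group sizes (a control arm and two alcohol
subgroups with closed/open neural tube, NTC/NTO), log-normal MAS5-style
signals, detection calls correlated with signal, planted down/up-regulated
probes, planted coherently-shifted gene sets, and planted all-present to
all-absent ("off") probes.

Both experiments share one per-probe true effect (the replication logic
assumes a common signal); the NTC subgroup expresses a configurable
fraction of the NTO effect, mirroring the milder phenotype. All randomness
flows from a single integer seed; identical seeds give bit-identical
outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
import json

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .io_formats import (
    ExpressionExperiment,
    GeneSet,
    GeneSetCollection,
    write_annotation,
    write_experiment,
    write_gmt,
)


@dataclass
class SimulationConfig:
    """Parameters of the paired-experiment simulation.

    Defaults reproduce the study design this package models: a 4-control /
    4-alcohol first experiment on the smaller platform and a 4 / 3 / 4
    second experiment on the full platform, ~63% of probes detectable, and
    planted effects strong enough (6x the per-array noise SD) for an
    adequately powered replication intersection at these tiny group sizes.
    """

    n_probes_platform_B: int = 20_000
    n_probes_platform_A: int = 13_810
    group_sizes_exp1: dict = field(
        default_factory=lambda: {"CONTROL": 4, "ALC_NTC": 2, "ALC_NTO": 2}
    )
    group_sizes_exp2: dict = field(
        default_factory=lambda: {"CONTROL": 4, "ALC_NTC": 3, "ALC_NTO": 4}
    )
    baseline_log2_mean: float = 7.0
    baseline_log2_sd: float = 1.5
    noise_log2_sd: float = 0.25
    n_planted_down: int = 150
    n_planted_up: int = 150
    planted_log2_effect: float = 2.0
    #: fraction of the full (NTO) effect expressed by the milder NTC arm
    subgroup_effect_ratio: float = 0.6
    n_planted_off: int = 20
    n_gene_sets: int = 30
    set_size_range: tuple = (10, 40)
    n_planted_enriched_sets: int = 3
    set_shift_log2: float = 0.75
    detection_threshold_log2: float = 6.5
    detection_flip_prob: float = 0.02
    seed: int = 1

    def validate(self) -> None:
        if self.n_probes_platform_A > self.n_probes_platform_B:
            raise ConfigurationError("platform A must be a subset of platform B")
        if self.n_probes_platform_A < 1:
            raise ConfigurationError("platform A must contain at least one probe")
        for name, sizes in (("exp1", self.group_sizes_exp1), ("exp2", self.group_sizes_exp2)):
            for grp, n in sizes.items():
                if n < 2:
                    raise ConfigurationError(
                        f"group {grp} in {name} has {n} samples; Welch needs >= 2"
                    )
        if not 0 <= self.detection_flip_prob <= 1:
            raise ConfigurationError("detection_flip_prob must be in [0, 1]")
        if self.baseline_log2_sd <= 0 or self.noise_log2_sd <= 0:
            raise ConfigurationError("standard deviations must be > 0")
        if not 0 <= self.subgroup_effect_ratio <= 1:
            raise ConfigurationError("subgroup_effect_ratio must be in [0, 1]")
        lo, hi = self.set_size_range
        if lo < 1 or hi < lo:
            raise ConfigurationError("set_size_range must be a (low, high) pair, low >= 1")
        if self.n_planted_enriched_sets > self.n_gene_sets:
            raise ConfigurationError("more planted enriched sets than gene sets")
        n_set_members_max = self.n_planted_enriched_sets * hi
        planted = (
            self.n_planted_down + self.n_planted_up + self.n_planted_off + n_set_members_max
        )
        if planted > self.n_probes_platform_A:
            raise ConfigurationError(
                f"planted categories need up to {planted} probes but platform A has "
                f"{self.n_probes_platform_A}"
            )


def null_config(n_probes: int = 20_000, seed: int = 1, **overrides) -> SimulationConfig:
    """A fully-null configuration: no planted effects of any kind, two
    experiments on one shared probe universe with 4 control vs 4 alcohol
    samples each. Used for calibration studies."""
    cfg = SimulationConfig(
        n_probes_platform_B=n_probes,
        n_probes_platform_A=n_probes,
        group_sizes_exp1={"CONTROL": 4, "ALC_NTC": 2, "ALC_NTO": 2},
        group_sizes_exp2={"CONTROL": 4, "ALC_NTC": 2, "ALC_NTO": 2},
        n_planted_down=0,
        n_planted_up=0,
        n_planted_off=0,
        n_planted_enriched_sets=0,
        seed=seed,
        **overrides,
    )
    return cfg


@dataclass
class GroundTruth:
    """What was planted, for recovery scoring downstream."""

    planted_down_ids: list
    planted_up_ids: list
    planted_off_ids: list
    planted_enriched_set_names: list
    true_log2_effect: pd.Series  # per probe; sign: + = higher under alcohol
    gene_sets: GeneSetCollection
    annotation: pd.DataFrame

    def to_json_dict(self) -> dict:
        return {
            "planted_down_ids": list(self.planted_down_ids),
            "planted_up_ids": list(self.planted_up_ids),
            "planted_off_ids": list(self.planted_off_ids),
            "planted_enriched_set_names": list(self.planted_enriched_set_names),
            "true_log2_effect": {
                k: float(v) for k, v in self.true_log2_effect.items() if v != 0
            },
        }


def _probe_id(i: int) -> str:
    return f"{100000 + i}_at"


def _gene_symbol(i: int) -> str:
    return f"Gene{i:05d}"


def _simulate_one(
    cfg: SimulationConfig,
    rng: np.random.Generator,
    prefix: str,
    probe_idx: np.ndarray,
    baseline: np.ndarray,
    effect: np.ndarray,
    off_mask: np.ndarray,
    group_sizes: dict,
    platform_id: str,
) -> ExpressionExperiment:
    order = ["CONTROL", "ALC_NTC", "ALC_NTO"]
    sample_ids, groups = [], []
    for grp in order:
        for j in range(group_sizes.get(grp, 0)):
            sample_ids.append(f"{prefix}_{grp.lower()}_{j + 1}")
            groups.append(grp)
    groups = pd.Series(groups, index=sample_ids)

    n_probes = len(probe_idx)
    base = baseline[probe_idx][:, None]
    eff = effect[probe_idx]
    # per-sample effect multiplier: 0 for control, ratio for NTC, 1 for NTO
    mult = np.array(
        [
            0.0 if g == "CONTROL" else (cfg.subgroup_effect_ratio if g == "ALC_NTC" else 1.0)
            for g in groups
        ]
    )
    log2sig = base + eff[:, None] * mult[None, :]
    log2sig = log2sig + rng.normal(0.0, cfg.noise_log2_sd, size=(n_probes, len(sample_ids)))

    # planted off probes: forced Present in every control array and Absent in
    # every alcohol array, regardless of flip noise
    off = off_mask[probe_idx]
    if off.any():
        is_ctrl = (groups == "CONTROL").to_numpy()
        hi = cfg.detection_threshold_log2 + 1.5
        lo = max(0.0, cfg.detection_threshold_log2 - 3.0)
        noise = rng.normal(0.0, cfg.noise_log2_sd, size=(int(off.sum()), len(sample_ids)))
        forced = np.where(is_ctrl[None, :], hi + np.abs(noise), lo - np.abs(noise))
        log2sig[off] = np.maximum(forced, 0.0)

    calls = np.where(log2sig >= cfg.detection_threshold_log2, "P", "A")
    flips = rng.random(size=calls.shape) < cfg.detection_flip_prob
    flips[off] = False
    calls = np.where(flips, np.where(calls == "P", "A", "P"), calls)

    probe_ids = [_probe_id(i) for i in probe_idx]
    signal = pd.DataFrame(2.0**log2sig, index=probe_ids, columns=sample_ids)
    detection = pd.DataFrame(calls, index=probe_ids, columns=sample_ids)
    return ExpressionExperiment(
        platform_id=platform_id, signal=signal, detection=detection, groups=groups
    )


def simulate_experiment_pair(
    cfg: SimulationConfig,
) -> tuple[ExpressionExperiment, ExpressionExperiment, GroundTruth]:
    """Generate the paired experiments and their ground truth.

    Experiment 1 is restricted to platform-A probes; Experiment 2 carries
    the full platform-B universe. Planted categories (down, up, off,
    enriched-set members) are disjoint and live on platform A so the
    cross-experiment intersection can recover them. Non-planted gene sets
    draw their members from probes with zero true effect, so only planted
    sets are truly coherent.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)

    nB, nA = cfg.n_probes_platform_B, cfg.n_probes_platform_A
    baseline = rng.normal(cfg.baseline_log2_mean, cfg.baseline_log2_sd, nB)

    # ---- plant disjoint categories on platform A -------------------------
    # Differential/coherent effects are planted only on probes expressed
    # above the detection threshold: an expression change is observable only
    # for a detectably expressed transcript, and the present filter would
    # otherwise silently drop part of the planted truth.
    expressed = np.flatnonzero(
        baseline[:nA] >= cfg.detection_threshold_log2 + 2 * cfg.noise_log2_sd
    )
    lo_, hi_ = cfg.set_size_range
    n_needed = (
        cfg.n_planted_down + cfg.n_planted_up + cfg.n_planted_off
        + cfg.n_planted_enriched_sets * hi_
    )
    if n_needed > len(expressed):
        raise ConfigurationError(
            f"planted categories need up to {n_needed} expressed platform-A "
            f"probes but only {len(expressed)} exceed the detection threshold"
        )
    perm_A = rng.permutation(expressed)
    cursor = 0

    def take(n):
        nonlocal cursor
        out = perm_A[cursor : cursor + n]
        cursor += n
        return out

    down_idx = take(cfg.n_planted_down)
    up_idx = take(cfg.n_planted_up)
    off_idx = take(cfg.n_planted_off)

    effect = np.zeros(nB)
    effect[down_idx] = -cfg.planted_log2_effect
    effect[up_idx] = cfg.planted_log2_effect

    off_mask = np.zeros(nB, dtype=bool)
    off_mask[off_idx] = True

    # ---- gene sets -------------------------------------------------------
    lo, hi = cfg.set_size_range
    gene_sets = GeneSetCollection(database="custom")
    planted_set_names = []
    for s in range(cfg.n_gene_sets):
        size = int(rng.integers(lo, hi + 1))
        planted = s < cfg.n_planted_enriched_sets
        if planted:
            members_idx = take(size)
            effect[members_idx] = -cfg.set_shift_log2  # coherent shift, down in alcohol
            name = f"SET{s:03d}_planted"
            planted_set_names.append(name)
        else:
            # sample among null platform-A probes (disjoint from all planted)
            pool = perm_A[cursor:]
            members_idx = rng.choice(pool, size=min(size, len(pool)), replace=False)
            name = f"SET{s:03d}"
        members = tuple(sorted(_gene_symbol(i) for i in members_idx))
        gene_sets.sets[name] = GeneSet(
            name=name,
            description="planted coherent shift" if planted else "null set",
            members=members,
        )

    annotation = pd.DataFrame(
        {
            "gene_symbol": [_gene_symbol(i) for i in range(nB)],
            "on_platform_A": [i < nA for i in range(nB)],
        },
        index=pd.Index([_probe_id(i) for i in range(nB)], name="probe_id"),
    )

    exp1 = _simulate_one(
        cfg, rng, "e1", np.arange(nA), baseline, effect, off_mask,
        cfg.group_sizes_exp1, platform_id="platform_A",
    )
    exp2 = _simulate_one(
        cfg, rng, "e2", np.arange(nB), baseline, effect, off_mask,
        cfg.group_sizes_exp2, platform_id="platform_B",
    )

    truth = GroundTruth(
        planted_down_ids=[_probe_id(i) for i in sorted(down_idx)],
        planted_up_ids=[_probe_id(i) for i in sorted(up_idx)],
        planted_off_ids=[_probe_id(i) for i in sorted(off_idx)],
        planted_enriched_set_names=planted_set_names,
        true_log2_effect=pd.Series(effect, index=[_probe_id(i) for i in range(nB)]),
        gene_sets=gene_sets,
        annotation=annotation,
    )
    return exp1, exp2, truth


def write_simulation(cfg: SimulationConfig, out_dir) -> dict:
    """Simulate and write the standard pipeline inputs under ``out_dir``:
    ``exp1/`` and ``exp2/`` (signals/calls/samples TSVs), ``annotation.tsv``,
    ``genesets.gmt`` and ``ground_truth.json``. Returns a path manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    exp1, exp2, truth = simulate_experiment_pair(cfg)
    manifest = {}
    for name, exp in (("exp1", exp1), ("exp2", exp2)):
        paths = write_experiment(exp, out / name)
        manifest[name] = {k: str(v) for k, v in paths.items()}
    manifest["annotation"] = str(write_annotation(truth.annotation, out / "annotation.tsv"))
    manifest["genesets"] = str(write_gmt(truth.gene_sets, out / "genesets.gmt"))
    gt_path = out / "ground_truth.json"
    with open(gt_path, "w", encoding="utf-8") as fh:
        json.dump(truth.to_json_dict(), fh, indent=1)
    manifest["ground_truth"] = str(gt_path)
    cfg_path = out / "sim_config.json"
    with open(cfg_path, "w", encoding="utf-8") as fh:
        json.dump({k: (list(v) if isinstance(v, tuple) else v) for k, v in asdict(cfg).items()}, fh, indent=1)
    manifest["config"] = str(cfg_path)
    return manifest
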