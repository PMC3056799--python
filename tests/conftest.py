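import numpy as np
import pandas as pd
import pytest

import replicaseq as rs
from replicaseq.differential import differential_table, get_contrast
from replicaseq.filtering import present_filter
from replicaseq.io_formats import ExpressionExperiment


def make_experiment(log2_signal, detection, groups, platform_id="platform_A"):
    """Build an ExpressionExperiment from log2 values and call strings."""
    probe_ids = [f"p{i:03d}_at" for i in range(len(log2_signal))]
    sample_ids = list(groups)
    signal = pd.DataFrame(
        2.0 ** np.asarray(log2_signal, float), index=probe_ids, columns=sample_ids
    )
    det = pd.DataFrame(
        [list(row) for row in detection], index=probe_ids, columns=sample_ids
    )
    return ExpressionExperiment(
        platform_id=platform_id,
        signal=signal,
        detection=det,
        groups=pd.Series(list(groups.values()), index=sample_ids),
    )


@pytest.fixture
def tiny_experiment():
    """4 probes x 8 samples (4 control, 2 NTC, 2 NTO) with varied calls."""
    groups = {
        "c1": "CONTROL", "c2": "CONTROL", "c3": "CONTROL", "c4": "CONTROL",
        "n1": "ALC_NTC", "n2": "ALC_NTC", "o1": "ALC_NTO", "o2": "ALC_NTO",
    }
    log2 = [
        [8.0, 8.1, 7.9, 8.0, 6.0, 6.1, 5.9, 6.0],   # down in alcohol
        [5.0, 5.1, 4.9, 5.0, 7.0, 7.1, 6.9, 7.0],   # up in alcohol
        [7.0, 7.1, 6.9, 7.0, 7.0, 7.1, 6.9, 7.0],   # flat
        [2.0, 2.1, 1.9, 2.0, 2.0, 2.1, 1.9, 2.0],   # low, absent everywhere
    ]
    detection = [
        "PPPPAAAA",
        "AAAAPPPP",
        "PPPPPPPP",
        "AAAAAAAA",
    ]
    return make_experiment(log2, detection, groups)


def run_replication(cfg):
    """Full filter -> Welch -> directional-intersection pipeline on a
    simulated pair; returns a dict of intermediates."""
    exp1, exp2, truth = rs.simulate_experiment_pair(cfg)
    f1, f2 = present_filter(exp1), present_filter(exp2)
    contrast = get_contrast("CTRL_vs_ALC")
    de1 = differential_table(exp1, contrast, alpha=0.05, probe_ids=f1.retained_probe_ids)
    de2 = differential_table(exp2, contrast, alpha=0.05, probe_ids=f2.retained_probe_ids)
    shared = sorted(
        set(f1.retained_probe_ids) & set(f2.retained_probe_ids) & set(exp1.probe_ids)
    )
    rep = rs.directional_intersection(de1, de2, shared, 0.05, 0.05)
    return {
        "exp1": exp1, "exp2": exp2, "truth": truth,
        "f1": f1, "f2": f2, "de1": de1, "de2": de2,
        "shared": shared, "report": rep, "contrast": contrast,
    }


@pytest.fixture(scope="session")
def default_pair():
    """The default simulated study (seed 1) run through the gene pipeline."""
    return run_replication(rs.SimulationConfig(seed=1))


@pytest.fixture(scope="session")
def small_config():
    """A scaled-down simulation for fast pipeline/GSEA tests."""
    return rs.SimulationConfig(
        n_probes_platform_B=1500,
        n_probes_platform_A=1200,
        n_planted_down=30,
        n_planted_up=30,
        n_planted_off=5,
        n_gene_sets=8,
        set_size_range=(5, 15),
        n_planted_enriched_sets=2,
        seed=11,
    )
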