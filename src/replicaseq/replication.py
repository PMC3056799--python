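"""Cross-experiment replication: directional intersection and on/off calls.

Instead of correcting for multiple testing within each small experiment,
the design requires a probe to be significant at a relaxed threshold in two
independent experiments *with the same direction of change*. Under the
null the chance of that is alpha1 * alpha2 / 2 per probe, which gives an
analytic expected overlap and hence an FDR for the intersected list.

On/off calling flags probes whose transcript is reliably detected in one
arm but undetected on *every* array of the other arm — expression switched
off (or de novo switched on) by treatment rather than merely shifted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd
from scipy import stats

from .errors import ConfigurationError
from .differential import Contrast
from .filtering import present_threshold
from .io_formats import ExpressionExperiment
from . import reports


@dataclass
class ReplicationReport:
    """Outcome of the directional two-experiment intersection."""

    n_common_tested: int
    alpha1: float
    alpha2: float
    n_down: int
    n_up: int
    shared_records: pd.DataFrame = field(repr=False)

    @property
    def p_joint(self) -> float:
        return reports.joint_null_probability(self.alpha1, self.alpha2)

    @property
    def expected_null(self) -> float:
        return self.n_common_tested * self.p_joint

    @property
    def expected_null_display(self) -> int:
        return reports.round_display(self.expected_null)

    @property
    def n_observed(self) -> int:
        return self.n_down + self.n_up

    @property
    def fdr(self) -> float | None:
        return reports.overlap_fdr(self.expected_null, self.n_observed)

    def to_dict(self) -> dict:
        return {
            "n_common_tested": self.n_common_tested,
            "alpha1": self.alpha1,
            "alpha2": self.alpha2,
            "p_joint": self.p_joint,
            "expected_null": self.expected_null,
            "expected_null_display": self.expected_null_display,
            "n_observed": self.n_observed,
            "n_down": self.n_down,
            "n_up": self.n_up,
            "fdr": self.fdr,
        }


def directional_intersection(
    de1: pd.DataFrame,
    de2: pd.DataFrame,
    shared_probes,
    alpha1: float = 0.05,
    alpha2: float = 0.05,
) -> ReplicationReport:
    """Intersect two differential tables requiring concordant direction.

    A probe replicates iff p1 <= alpha1, p2 <= alpha2, and both directions
    agree and are not "none". ``shared_probes`` is the commonly tested
    universe (present-filtered in both experiments, on the shared
    platform); both tables must cover it.
    """
    shared_probes = list(shared_probes)
    if not shared_probes:
        raise ConfigurationError("shared probe universe is empty")
    if not (0 <= alpha1 <= 1 and 0 <= alpha2 <= 1):
        raise ConfigurationError("alphas must be in [0, 1]")
    missing1 = set(shared_probes) - set(de1.index)
    missing2 = set(shared_probes) - set(de2.index)
    if missing1 or missing2:
        raise ConfigurationError(
            f"differential tables do not cover the shared universe "
            f"({len(missing1)} missing in exp1, {len(missing2)} in exp2)"
        )
    a = de1.loc[shared_probes]
    b = de2.loc[shared_probes]
    hit = (
        (a["p_value"] <= alpha1)
        & (b["p_value"] <= alpha2)
        & (a["direction"] == b["direction"])
        & (a["direction"] != "none")
    )
    shared = pd.DataFrame(
        {
            "probe_id": list(a.index[hit]),
            "direction": a.loc[hit, "direction"].to_numpy(),
            "fold_exp1": a.loc[hit, "signed_fold"].to_numpy(),
            "fold_exp2": b.loc[hit, "signed_fold"].to_numpy(),
            "p_exp1": a.loc[hit, "p_value"].to_numpy(),
            "p_exp2": b.loc[hit, "p_value"].to_numpy(),
        }
    ).sort_values(["p_exp1", "probe_id"], kind="mergesort")
    return ReplicationReport(
        n_common_tested=len(shared_probes),
        alpha1=alpha1,
        alpha2=alpha2,
        n_down=int((shared["direction"] == "down").sum()),
        n_up=int((shared["direction"] == "up").sum()),
        shared_records=shared.reset_index(drop=True),
    )


def onoff_calls(
    exp: ExpressionExperiment,
    contrast: Contrast,
    de_records: pd.DataFrame,
    p_mode: str = "welch",
    rule: str = "ceil",
) -> pd.DataFrame:
    """Probes switched off (or on) by the test condition.

    ``off_in_test``: Present on at least half the reference-arm arrays
    (ceil rule, as in the analysis filter) and Present on *zero* test-arm
    arrays; ``on_in_test`` is the mirror image. The attached p-value is the
    Welch p for the same contrast (``p_mode="welch"``) or a Fisher exact
    test on the Present/Absent counts (``p_mode="fisher"``). Sorted by p.
    """
    if p_mode not in ("welch", "fisher"):
        raise ConfigurationError(f"unknown p_mode {p_mode!r}")
    ref_samples = exp.samples_in(contrast.reference)
    test_samples = exp.samples_in(contrast.test)
    if not ref_samples or not test_samples:
        raise ConfigurationError(f"contrast {contrast.name}: empty arm")
    present = exp.present_mask()
    ref_p = present[ref_samples].sum(axis=1)
    test_p = present[test_samples].sum(axis=1)
    need_ref = present_threshold(len(ref_samples), rule=rule)
    need_test = present_threshold(len(test_samples), rule=rule)

    off = (ref_p >= need_ref) & (test_p == 0)
    on = (test_p >= need_test) & (ref_p == 0)

    rows = []
    for probe in exp.probe_ids:
        if off[probe]:
            status = "off_in_test"
        elif on[probe]:
            status = "on_in_test"
        else:
            continue
        if p_mode == "welch":
            p = (
                float(de_records.loc[probe, "p_value"])
                if probe in de_records.index
                else float("nan")
            )
        else:
            table = [
                [int(ref_p[probe]), len(ref_samples) - int(ref_p[probe])],
                [int(test_p[probe]), len(test_samples) - int(test_p[probe])],
            ]
            p = float(stats.fisher_exact(table)[1])
        rows.append(
            {"probe_id": probe, "contrast": contrast.name, "status": status, "p_value": p}
        )
    out = pd.DataFrame(rows, columns=["probe_id", "contrast", "status", "p_value"])
    return out.sort_values(["p_value", "probe_id"], kind="mergesort").reset_index(drop=True)
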