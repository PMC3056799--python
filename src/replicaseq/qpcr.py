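"""Relative quantification of qRT-PCR data.

Two quantification routes are implemented:

* the comparative ΔΔCt method — per sample, the target gene's cycle
  threshold (Ct) is normalised to a reference gene (Gapdh in the study
  design this models): ΔCt = Ct_target - Ct_reference. Group ΔΔCt is the
  mean treated ΔCt minus the mean control ΔCt, and the relative quantity is
  2^-ΔΔCt, mapped to the signed-fold convention (0.5 -> -2.0).
* the standard-curve method — a least-squares line Ct = a*log10(amount) + b
  fitted to a dilution series; an unknown's amount is 10^((Ct - b)/a). The
  amplification efficiency 10^(-1/a) - 1 is reported for QC (a perfect
  doubling has slope -3.32 and efficiency 1).

Group comparison follows one-way ANOVA with pairwise pooled-variance
Student t tests.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError, DataError, StatisticsError
from .differential import signed_fold_from_ratio

QPCR_COLUMNS = ("sample", "group", "gene", "replicate", "ct")


def read_qpcr_table(path) -> pd.DataFrame:
    """Read a measurement table (sample, group, gene, replicate, ct)."""
    df = pd.read_csv(Path(path), sep="\t")
    missing = set(QPCR_COLUMNS) - set(df.columns)
    if missing:
        raise DataError(f"qpcr table missing columns {sorted(missing)}")
    if (df["ct"] <= 0).any():
        bad = df.loc[df["ct"] <= 0].iloc[0]
        raise DataError(f"non-positive Ct for sample {bad['sample']!r}")
    return df


def delta_ct(measurements: pd.DataFrame, target_gene: str, reference_gene: str) -> pd.DataFrame:
    """Per-sample ΔCt = mean Ct(target) - mean Ct(reference).

    Replicate Cts are averaged within a sample first. A sample with target
    measurements but no reference Ct is a :class:`DataError`.
    """
    df = measurements
    tgt = df[df["gene"] == target_gene].groupby("sample")["ct"].mean()
    ref = df[df["gene"] == reference_gene].groupby("sample")["ct"].mean()
    if tgt.empty:
        raise DataError(f"no measurements for target gene {target_gene!r}")
    missing = set(tgt.index) - set(ref.index)
    if missing:
        raise DataError(
            f"missing reference gene {reference_gene!r} Ct for sample(s) "
            f"{sorted(missing)}"
        )
    groups = df.drop_duplicates("sample").set_index("sample")["group"]
    out = pd.DataFrame(
        {"delta_ct": tgt - ref.loc[tgt.index], "group": groups.loc[tgt.index]}
    )
    out.index.name = "sample"
    return out


def ddct(
    measurements: pd.DataFrame,
    target_gene: str,
    reference_gene: str = "Gapdh",
    control_group: str = "CONTROL",
) -> pd.DataFrame:
    """Comparative ΔΔCt quantification of ``target_gene`` per group.

    Returns one row per group with columns ``delta_ct`` (group mean),
    ``delta_delta_ct`` (relative to the control group), ``relative_quantity``
    (2^-ΔΔCt) and ``signed_fold``. The control row has ΔΔCt 0 and fold 1.
    """
    per_sample = delta_ct(measurements, target_gene, reference_gene)
    if control_group not in set(per_sample["group"]):
        raise ConfigurationError(f"control group {control_group!r} not in data")
    group_means = per_sample.groupby("group")["delta_ct"].mean()
    ctrl = group_means[control_group]
    rows = []
    for grp, dct in group_means.items():
        dd = dct - ctrl
        quantity = 2.0 ** (-dd)
        rows.append(
            {
                "gene": target_gene,
                "group": grp,
                "delta_ct": dct,
                "delta_delta_ct": dd,
                "relative_quantity": quantity,
                "signed_fold": signed_fold_from_ratio(quantity),
            }
        )
    return pd.DataFrame(rows).set_index("group")


@dataclass
class StandardCurve:
    """A fitted dilution-series line Ct = slope*log10(amount) + intercept."""

    slope: float
    intercept: float
    r_squared: float

    @property
    def efficiency(self) -> float:
        """Amplification efficiency, 1.0 = perfect doubling per cycle."""
        return 10.0 ** (-1.0 / self.slope) - 1.0

    def quantify(self, ct: float) -> float:
        """Relative input amount for an observed Ct."""
        return 10.0 ** ((ct - self.intercept) / self.slope)


def fit_standard_curve(curve_points) -> StandardCurve:
    """Least-squares fit of (log10 input amount, Ct) dilution points.

    Requires >= 3 points spanning >= 2 log10 units; a near-flat slope
    (|a| < 0.1) is a fitting error.
    """
    pts = np.asarray(curve_points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 3:
        raise ConfigurationError("need >= 3 (log10 amount, Ct) curve points")
    x, y = pts[:, 0], pts[:, 1]
    if x.max() - x.min() < 2.0:
        raise ConfigurationError("curve must span >= 2 log10 units of input")
    res = stats.linregress(x, y)
    if abs(res.slope) < 0.1:
        raise StatisticsError(f"standard curve is flat (slope {res.slope:.3g})")
    return StandardCurve(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
    )


def standard_curve_quantify(curve_points, unknown_ct: float) -> float:
    """Convenience: fit the curve and quantify one unknown Ct."""
    return fit_standard_curve(curve_points).quantify(unknown_ct)


def group_compare(values_by_group: dict) -> tuple[float, dict]:
    """One-way ANOVA p plus pairwise pooled-variance Student t p-values.

    Groups that are all one identical constant have zero between-group
    variance; that degenerate case is reported as p = 1 (no evidence of any
    difference) rather than NaN.
    """
    groups = {g: np.asarray(v, dtype=float) for g, v in values_by_group.items()}
    if len(groups) < 2:
        raise ConfigurationError("need at least 2 groups")
    for g, v in groups.items():
        if len(v) < 2:
            raise ConfigurationError(f"group {g!r} has fewer than 2 values")

    all_values = np.concatenate(list(groups.values()))
    if np.ptp(all_values) == 0:
        anova_p = 1.0
    else:
        anova_p = float(stats.f_oneway(*groups.values()).pvalue)
        if np.isnan(anova_p):
            anova_p = 1.0

    pairwise = {}
    for g1, g2 in itertools.combinations(sorted(groups), 2):
        a, b = groups[g1], groups[g2]
        if np.ptp(np.concatenate([a, b])) == 0:
            p = 1.0
        else:
            p = float(stats.ttest_ind(a, b, equal_var=True).pvalue)
            if np.isnan(p):
                p = 1.0
        pairwise[(g1, g2)] = p
    return anova_p, pairwise
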