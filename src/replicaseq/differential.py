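"""Per-probe Welch tests and signed fold changes for each contrast.

Signals are log2-transformed (with a floor for near-zero MAS5 values)
before testing. The fold change is the antilog of the difference of group
mean log2 signals — a geometric-mean ratio — mapped to the signed
convention used for array tables: ratios below 1 are reported as -1/ratio,
so a halving is -2.0.

No per-experiment multiple-testing correction is applied at the probe
level: the cross-experiment directional intersection (see
:mod:`replicaseq.replication`) is the error control, so each experiment is
run at a deliberately relaxed threshold to limit false negatives.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError, StatisticsError
from .io_formats import ExpressionExperiment


@dataclass(frozen=True)
class Contrast:
    """A two-arm comparison: reference groups vs test groups."""

    name: str
    reference: frozenset
    test: frozenset
    ref_label: str
    test_label: str

    def __post_init__(self):
        if not self.reference or not self.test:
            raise ConfigurationError(f"contrast {self.name}: both arms must be non-empty")
        if self.reference & self.test:
            raise ConfigurationError(f"contrast {self.name}: arms overlap")

    def flipped(self) -> "Contrast":
        return Contrast(
            name=self.name,
            reference=self.test,
            test=self.reference,
            ref_label=self.test_label,
            test_label=self.ref_label,
        )


#: The four study contrasts. Reference is always the control-like arm.
CONTRASTS: dict[str, Contrast] = {
    "CTRL_vs_ALC": Contrast(
        "CTRL_vs_ALC", frozenset({"CONTROL"}), frozenset({"ALC_NTC", "ALC_NTO"}),
        "CONTROL", "ALC",
    ),
    "CTRL_vs_NTC": Contrast(
        "CTRL_vs_NTC", frozenset({"CONTROL"}), frozenset({"ALC_NTC"}),
        "CONTROL", "ALC_NTC",
    ),
    "CTRL_vs_NTO": Contrast(
        "CTRL_vs_NTO", frozenset({"CONTROL"}), frozenset({"ALC_NTO"}),
        "CONTROL", "ALC_NTO",
    ),
    "NTC_vs_NTO": Contrast(
        "NTC_vs_NTO", frozenset({"ALC_NTC"}), frozenset({"ALC_NTO"}),
        "ALC_NTC", "ALC_NTO",
    ),
}


def get_contrast(name: str) -> Contrast:
    key = name.upper().replace("-", "_")
    lookup = {k.upper(): k for k in CONTRASTS}
    if key not in lookup:
        raise ConfigurationError(
            f"unknown contrast {name!r}; choose from {sorted(CONTRASTS)}"
        )
    return CONTRASTS[lookup[key]]


def log_transform(exp: ExpressionExperiment, floor: float = 1.0) -> pd.DataFrame:
    """log2 of the signal matrix with values floored at ``floor`` (> 0)."""
    if floor <= 0:
        raise ConfigurationError("floor must be > 0")
    return np.log2(exp.signal.clip(lower=floor))


def signed_fold_from_ratio(ratio: float) -> float:
    """Map a ratio to the signed fold convention: 0.5 -> -2.0, 2.0 -> 2.0."""
    if ratio <= 0:
        raise ValueError("ratio must be positive")
    return float(ratio) if ratio >= 1 else float(-1.0 / ratio)


def signed_fold_from_log2(delta_log2: float) -> float:
    """Signed fold change from a log2 difference (test minus reference)."""
    mag = 2.0 ** abs(delta_log2)
    return mag if delta_log2 >= 0 else -mag


def _welch_arrays(x: np.ndarray, y: np.ndarray):
    """Vectorised Welch statistics along the last axis.

    Returns (t, df, p); t is positive when mean(x) > mean(y). Rows where
    both arms have zero variance get t = 0, p = 1 when the means agree and
    an effectively-zero p when they differ.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    nx, ny = x.shape[-1], y.shape[-1]
    if nx < 2 or ny < 2:
        raise StatisticsError("Welch test needs at least 2 observations per group")
    mx, my = x.mean(axis=-1), y.mean(axis=-1)
    vx = x.var(axis=-1, ddof=1)
    vy = y.var(axis=-1, ddof=1)
    se2 = vx / nx + vy / ny
    diff = mx - my
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / np.sqrt(se2)
        df = se2**2 / (vx**2 / (nx**2 * (nx - 1)) + vy**2 / (ny**2 * (ny - 1)))
        # Welch–Satterthwaite df always lies in [min(n)-1, nx+ny-2]; clipping
        # only repairs floating-point under/overflow at extreme variance ratios
        lo, hi = float(min(nx, ny) - 1), float(nx + ny - 2)
        df = np.where(np.isfinite(df), np.clip(df, lo, hi), lo)
        zero_se = se2 == 0
        equal = zero_se & (diff == 0)
        unequal = zero_se & (diff != 0)
        t = np.where(equal, 0.0, t)
        t = np.where(unequal, np.sign(diff) * np.inf, t)
        df = np.where(zero_se, hi, df)
    p = 2.0 * stats.t.sf(np.abs(t), df)
    p = np.where(equal, 1.0, p)
    # keep p in (0, 1] as documented even for infinite t
    p = np.maximum(p, np.finfo(float).tiny)
    return t, df, p


def welch_test(x, y) -> tuple[float, float, float]:
    """Welch's unequal-variance t-test, two-sided.

    t = (mean x - mean y) / sqrt(sx^2/nx + sy^2/ny) with sample variances,
    degrees of freedom by Welch–Satterthwaite, p from Student's t. Groups
    with identical constant values give t = 0, p = 1.
    """
    t, df, p = _welch_arrays(np.atleast_1d(np.asarray(x, float)),
                             np.atleast_1d(np.asarray(y, float)))
    return float(t), float(df), float(p)


def differential_table(
    exp: ExpressionExperiment,
    contrast: Contrast,
    alpha: float = 0.05,
    floor: float = 1.0,
    probe_ids=None,
) -> pd.DataFrame:
    """Welch test and signed fold change for every (retained) probe.

    Returns a DataFrame with one row per probe: ``probe_id``, ``contrast``,
    ``mean_log2_ref``, ``mean_log2_test``, ``welch_t``, ``welch_df``,
    ``p_value``, ``signed_fold``, ``direction``. ``welch_t`` is oriented
    test-minus-reference so its sign agrees with the fold change; direction
    is "down"/"up" only when p <= alpha, else "none".
    """
    if not 0 <= alpha <= 1:
        raise ConfigurationError("alpha must be in [0, 1]")
    log2 = log_transform(exp, floor=floor)
    if probe_ids is not None:
        log2 = log2.loc[list(probe_ids)]
    ref_samples = exp.samples_in(contrast.reference)
    test_samples = exp.samples_in(contrast.test)
    if len(ref_samples) < 2 or len(test_samples) < 2:
        raise StatisticsError(
            f"contrast {contrast.name} needs >= 2 samples per arm in "
            f"experiment {exp.platform_id} "
            f"(got {len(ref_samples)} vs {len(test_samples)})"
        )
    ref = log2[ref_samples].to_numpy()
    test = log2[test_samples].to_numpy()
    t, df, p = _welch_arrays(test, ref)  # oriented test - reference
    delta = test.mean(axis=1) - ref.mean(axis=1)
    signed_fold = np.where(delta >= 0, 2.0**np.abs(delta), -(2.0 ** np.abs(delta)))
    direction = np.where(
        p <= alpha, np.where(delta < 0, "down", "up"), "none"
    )
    # a zero difference can never be a directional call
    direction = np.where((p <= alpha) & (delta == 0), "none", direction)
    return pd.DataFrame(
        {
            "probe_id": log2.index,
            "contrast": contrast.name,
            "mean_log2_ref": ref.mean(axis=1),
            "mean_log2_test": test.mean(axis=1),
            "welch_t": t,
            "welch_df": df,
            "p_value": p,
            "signed_fold": signed_fold,
            "direction": direction,
        }
    ).set_index("probe_id", drop=False)
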