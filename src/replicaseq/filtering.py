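"""Detection-call ("present") filtering.

A probe set is kept for analysis only if it is called Present on at least
half of the arrays in at least one experimental condition, which screens out
probe sets whose signal is mostly noise. "At least half" with an odd number
of arrays defaults to count >= ceil(n/2) (the strictest reading); a
floor(n/2) variant is available for sensitivity analysis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

from .errors import ConfigurationError
from .io_formats import ExpressionExperiment, GROUP_LABELS

#: Default conditions: the control arm and the pooled alcohol arm.
DEFAULT_CONDITIONS: tuple[frozenset[str], ...] = (
    frozenset({"CONTROL"}),
    frozenset({"ALC_NTC", "ALC_NTO"}),
)

#: Subgroup-level conditions (each study arm on its own).
SUBGROUP_CONDITIONS: tuple[frozenset[str], ...] = (
    frozenset({"CONTROL"}),
    frozenset({"ALC_NTC"}),
    frozenset({"ALC_NTO"}),
)


@dataclass
class FilterResult:
    """Outcome of the present filter on one experiment."""

    retained_probe_ids: list[str]
    n_input: int
    n_retained: int
    per_condition_present: dict[str, int] = field(default_factory=dict)

    @property
    def fraction_retained(self) -> float:
        return self.n_retained / self.n_input if self.n_input else 0.0

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_retained": self.n_retained,
            "fraction_retained": self.fraction_retained,
            "per_condition_present": self.per_condition_present,
        }


def _condition_name(condition: frozenset[str]) -> str:
    return "+".join(sorted(condition))


def present_threshold(n_samples: int, rule: str = "ceil") -> int:
    """Minimum number of Present calls meaning "at least half of n arrays"."""
    if rule == "ceil":
        return math.ceil(n_samples / 2)
    if rule == "floor":
        return max(1, math.floor(n_samples / 2))
    raise ConfigurationError(f"unknown half-rule {rule!r}; use 'ceil' or 'floor'")


def present_filter(
    exp: ExpressionExperiment,
    conditions: Sequence[Iterable[str]] = DEFAULT_CONDITIONS,
    rule: str = "ceil",
) -> FilterResult:
    """Retain probes Present on >= half the arrays of some condition.

    ``conditions`` is a list of sets of group labels; each set is pooled into
    one condition. A probe is retained iff for at least one condition the
    number of its Present calls among that condition's samples reaches the
    half threshold.
    """
    present = exp.present_mask()
    retained = pd.Series(False, index=exp.probe_ids)
    per_condition: dict[str, int] = {}
    for cond in conditions:
        cond = frozenset(cond)
        unknown = cond - set(GROUP_LABELS)
        if unknown:
            raise ConfigurationError(f"condition references unknown groups {sorted(unknown)}")
        samples = exp.samples_in(cond)
        if not samples:
            raise ConfigurationError(
                f"condition {_condition_name(cond)} has no samples in experiment "
                f"{exp.platform_id}"
            )
        need = present_threshold(len(samples), rule=rule)
        ok = present[samples].sum(axis=1) >= need
        per_condition[_condition_name(cond)] = int(ok.sum())
        retained |= ok
    return FilterResult(
        retained_probe_ids=list(exp.probe_ids[retained]),
        n_input=len(exp.probe_ids),
        n_retained=int(retained.sum()),
        per_condition_present=per_condition,
    )
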