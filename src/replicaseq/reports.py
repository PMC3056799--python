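"""Analytic report utilities: null overlap arithmetic and display helpers.

Two independent experiments each tested at level alpha agree by chance with
probability alpha1 * alpha2, and agree *in direction* with half of that, so
the joint directional null probability is alpha1 * alpha2 / 2. Multiplying
by the number of commonly tested genes (or gene-set tests) gives the
expected chance overlap, and expected / observed is the replication FDR.
"""

from __future__ import annotations

from typing import Iterable


def joint_null_probability(alpha1: float, alpha2: float) -> float:
    """P(significant in both experiments with concordant direction | null)."""
    return alpha1 * alpha2 * 0.5


def expected_null_overlap(n_common_tested: int, alpha1: float, alpha2: float) -> float:
    """Expected number of chance directional overlaps among n common genes."""
    return n_common_tested * joint_null_probability(alpha1, alpha2)


def overlap_fdr(expected_null: float, n_observed: int) -> float | None:
    """Replication FDR = expected chance overlap / observed overlap.

    Undefined (None) when nothing was observed — never reported as 0.
    """
    if n_observed == 0:
        return None
    return expected_null / n_observed


def gsea_test_count(set_counts: Iterable[int], n_contrasts: int) -> int:
    """Total number of set-level tests: n_contrasts x total sets."""
    return n_contrasts * sum(set_counts)


def round_display(x: float) -> int:
    """Nearest-integer display rounding for expected counts (17.26 -> 17)."""
    import math

    return int(math.floor(x + 0.5))


def percentage(k: int, n: int, digits: int = 0) -> float:
    """k out of n as a percentage, rounded to ``digits`` decimals."""
    if n <= 0:
        raise ValueError("denominator must be positive")
    return round(100.0 * k / n, digits) if digits else float(round(100.0 * k / n))
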