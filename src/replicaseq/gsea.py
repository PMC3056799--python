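"""Gene set enrichment analysis with a running-sum statistic.

Genes are ranked by their association with the contrast (signal-to-noise
ratio or Welch t, oriented so positive means higher in the reference/control
arm). Walking down the ranked list, the running sum gains 1/n_hits at each
set member ("hit") and loses 1/(N - n_hits) at each non-member ("miss") —
the classic unweighted Kolmogorov–Smirnov form. The enrichment score (ES)
is the maximum of this profile: a set concentrated near the top of the list
peaks high. The test is one-sided (top enrichment only); enrichment in the
other arm is tested by flipping the contrast orientation.

Significance comes from a permutation test on the peak height. The default
"gene" mode draws random member sets of equal size from the ranked
universe; "phenotype" mode re-labels samples, enumerating all distinct
relabelings when there are fewer than the requested number of permutations
(with 4-vs-4 arms there are only C(8,4) = 70). Member genes at ranks up to
the peak position form the leading edge — the members that drive the
signal.

A set-level replication report mirrors the gene-level intersection: a
(set, contrast) pair replicates when it is significant with the same
enrichment direction in both experiments, and the expected chance overlap
is n_tests * alpha^2 / 2.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, StatisticsError
from .differential import Contrast, log_transform, _welch_arrays
from .io_formats import ExpressionExperiment, GeneSetCollection
from . import reports

log = logging.getLogger(__name__)


@dataclass
class RankedList:
    """Genes ordered best-to-worst by association with the reference arm."""

    contrast: str
    genes: np.ndarray  # ordered gene ids
    scores: np.ndarray  # matching metric values, descending

    def __len__(self) -> int:
        return len(self.genes)

    @property
    def rank_of(self) -> dict:
        return {g: i + 1 for i, g in enumerate(self.genes)}


@dataclass
class GseaResult:
    set_name: str
    contrast: str
    experiment: str
    database: str
    size_in_universe: int
    es_peak: float
    peak_position: int
    p_value: float
    n_permutations: int
    enriched_in: str
    leading_edge: list = field(default_factory=list)
    es_profile: np.ndarray | None = field(default=None, repr=False)


@dataclass
class SetReplicationReport:
    """Chance-overlap accounting for set-level cross-experiment replication."""

    n_tests_total: int
    alpha: float
    n_shared_observed: int
    shared_sets: list  # of (set_name, contrast, enriched_in)

    @property
    def expected_shared(self) -> float:
        return self.n_tests_total * self.alpha * self.alpha * 0.5

    @property
    def expected_shared_display(self) -> int:
        return reports.round_display(self.expected_shared)

    @property
    def fdr(self) -> float | None:
        return reports.overlap_fdr(self.expected_shared, self.n_shared_observed)

    @property
    def fdr_display(self) -> float | None:
        """FDR computed from the display-rounded expectation (3/15 -> 20%),
        matching how such reports quote the arithmetic."""
        return reports.overlap_fdr(
            float(self.expected_shared_display), self.n_shared_observed
        )

    def to_dict(self) -> dict:
        return {
            "n_tests_total": self.n_tests_total,
            "alpha": self.alpha,
            "expected_shared": self.expected_shared,
            "expected_shared_display": self.expected_shared_display,
            "n_shared_observed": self.n_shared_observed,
            "fdr": self.fdr,
            "fdr_display": self.fdr_display,
            "shared_sets": [list(s) for s in self.shared_sets],
        }


# ---------------------------------------------------------------------------
# ranking
# ---------------------------------------------------------------------------

def _metric_scores(ref: np.ndarray, test: np.ndarray, metric: str) -> np.ndarray:
    """Per-row association score, positive = higher in the reference arm."""
    if metric == "signal_to_noise":
        diff = ref.mean(axis=1) - test.mean(axis=1)
        denom = ref.std(axis=1, ddof=1) + test.std(axis=1, ddof=1)
        zero = denom == 0
        if zero.any():
            log.info("%d genes with zero variance in both arms: metric set to 0",
                     int(zero.sum()))
        with np.errstate(divide="ignore", invalid="ignore"):
            s = np.where(zero, 0.0, diff / np.where(zero, 1.0, denom))
        return s
    if metric == "welch_t":
        t, _, _ = _welch_arrays(ref, test)
        return np.where(np.isfinite(t), t, np.sign(t) * 1e12)
    raise ConfigurationError(f"unknown ranking metric {metric!r}")


def rank_genes(
    exp: ExpressionExperiment,
    contrast: Contrast,
    metric: str = "signal_to_noise",
    annotation: pd.DataFrame | None = None,
    probe_ids: Sequence[str] | None = None,
    floor: float = 1.0,
) -> RankedList:
    """Rank the (filtered) gene universe by association with the contrast.

    Probes are collapsed to genes by keeping the probe with the largest
    absolute metric; without an annotation each probe is its own gene.
    Ties are broken lexicographically by gene id, so the ranking is fully
    deterministic.
    """
    log2 = log_transform(exp, floor=floor)
    if probe_ids is not None:
        log2 = log2.loc[list(probe_ids)]
    ref_samples = exp.samples_in(contrast.reference)
    test_samples = exp.samples_in(contrast.test)
    if len(ref_samples) < 2 or len(test_samples) < 2:
        raise StatisticsError(
            f"contrast {contrast.name} needs >= 2 samples per arm"
        )
    scores = _metric_scores(log2[ref_samples].to_numpy(),
                            log2[test_samples].to_numpy(), metric)
    df = pd.DataFrame({"score": scores}, index=log2.index)
    if annotation is not None:
        df["gene"] = annotation.loc[df.index, "gene_symbol"]
        df = df[df["gene"] != ""]
        idx = df.groupby("gene")["score"].apply(lambda s: s.abs().idxmax())
        df = df.loc[idx.values].set_index("gene")
    else:
        df.index.name = "gene"
    df = df.sort_values("score", ascending=False, kind="mergesort")
    # deterministic tie-break by gene id within equal scores
    df = df.iloc[
        np.lexsort((df.index.to_numpy(), -df["score"].to_numpy()), axis=0)
    ]
    return RankedList(
        contrast=contrast.name,
        genes=df.index.to_numpy(),
        scores=df["score"].to_numpy(),
    )


# ---------------------------------------------------------------------------
# enrichment score
# ---------------------------------------------------------------------------

def enrichment_score(
    ranked: RankedList | Sequence[str], members: Iterable[str]
) -> tuple[np.ndarray, float, int]:
    """Running-sum profile, its peak and the peak's rank (1-based).

    Hits gain 1/n_hits, misses lose 1/(N - n_hits); the profile telescopes
    back to 0 at the end when every member is in the universe. Members
    absent from the universe are dropped with a warning. The peak is the
    profile maximum; ties resolve to the first occurrence.
    """
    genes = ranked.genes if isinstance(ranked, RankedList) else np.asarray(list(ranked))
    members = set(members)
    in_universe = members & set(genes.tolist())
    dropped = len(members) - len(in_universe)
    if dropped:
        log.warning("%d set members absent from the ranked universe (dropped)", dropped)
    if not in_universe:
        raise StatisticsError("no set members present in the ranked universe")
    N = len(genes)
    k = len(in_universe)
    if k == N:
        raise StatisticsError("gene set covers the whole universe; ES undefined")
    is_hit = np.fromiter((g in in_universe for g in genes), dtype=bool, count=N)
    steps = np.where(is_hit, 1.0 / k, -1.0 / (N - k))
    profile = np.cumsum(steps)
    peak_idx = int(np.argmax(profile))
    return profile, float(profile[peak_idx]), peak_idx + 1


def leading_edge(ranked: RankedList, members: Iterable[str], peak_position: int) -> list[str]:
    """Set members at ranks up to (and including) the ES peak."""
    members = set(members)
    return [g for g in ranked.genes[:peak_position] if g in members]


def _null_peaks_gene_mode(
    N: int, k: int, n_perm: int, rng: np.random.Generator
) -> np.ndarray:
    """ES peaks of ``n_perm`` random k-subsets of an N-gene universe.

    Uses the fact that local maxima of the running sum occur immediately
    after hits: with sorted hit positions pos_i (1-based), the value there
    is i/k - (pos_i - i)/(N - k). When the first rank is a miss the profile
    also visits -1/(N-k) before any hit, which matters only for sets packed
    at the very bottom.
    """
    miss = 1.0 / (N - k)
    i_over_k = np.arange(1, k + 1) / k
    peaks = np.empty(n_perm)
    for j in range(n_perm):
        pos = np.sort(rng.choice(N, size=k, replace=False)) + 1
        after_hit = i_over_k - (pos - np.arange(1, k + 1)) * miss
        peak = after_hit.max()
        if pos[0] > 1:
            peak = max(peak, -miss)
        peaks[j] = peak
    return peaks


def _distinct_relabelings(groups: pd.Series, ref: set, test: set):
    """All distinct assignments of the pooled contrast samples into arms of
    the observed sizes. Yields (ref_samples, test_samples) tuples."""
    samples = [s for s in groups.index if groups[s] in ref | test]
    n_ref = sum(groups[s] in ref for s in samples)
    for combo in itertools.combinations(range(len(samples)), n_ref):
        ref_s = [samples[i] for i in combo]
        test_s = [s for i, s in enumerate(samples) if i not in set(combo)]
        yield ref_s, test_s


def permutation_pvalue(
    exp: ExpressionExperiment,
    contrast: Contrast,
    members: Iterable[str],
    n_perm: int = 999,
    mode: str = "gene",
    seed: int | None = None,
    metric: str = "signal_to_noise",
    annotation: pd.DataFrame | None = None,
    probe_ids: Sequence[str] | None = None,
    ranked: RankedList | None = None,
) -> float:
    """Permutation p-value for the observed ES peak.

    p = (1 + #{permutation peak >= observed peak}) / (1 + n_perm), bounded
    below by 1/(n_perm + 1). Phenotype mode enumerates all distinct
    relabelings when they number fewer than ``n_perm`` and then reports
    #{peak >= observed}/n_distinct (the identity relabeling included).
    """
    if n_perm < 100:
        raise ConfigurationError("n_perm must be >= 100")
    if mode not in ("gene", "phenotype"):
        raise ConfigurationError(f"unknown permutation mode {mode!r}")
    if ranked is None:
        ranked = rank_genes(exp, contrast, metric=metric, annotation=annotation,
                            probe_ids=probe_ids)
    _, obs_peak, _ = enrichment_score(ranked, members)
    members_in = set(members) & set(ranked.genes.tolist())
    N, k = len(ranked), len(members_in)
    rng = np.random.default_rng(seed)

    if mode == "gene":
        null = _null_peaks_gene_mode(N, k, n_perm, rng)
        return float((1 + int((null >= obs_peak - 1e-12).sum())) / (1 + n_perm))

    # phenotype mode
    relabelings = list(_distinct_relabelings(exp.groups, set(contrast.reference),
                                             set(contrast.test)))
    log2 = log_transform(exp)
    if probe_ids is not None:
        log2 = log2.loc[list(probe_ids)]
    exhaustive = len(relabelings) <= n_perm
    if not exhaustive:
        idx = rng.choice(len(relabelings), size=n_perm, replace=False)
        relabelings = [relabelings[i] for i in idx]
    peaks = []
    for ref_s, test_s in relabelings:
        if len(ref_s) < 2 or len(test_s) < 2:
            continue
        scores = _metric_scores(log2[ref_s].to_numpy(), log2[test_s].to_numpy(), metric)
        order = np.lexsort((log2.index.to_numpy(), -scores))
        genes = log2.index.to_numpy()[order]
        _, peak, _ = enrichment_score(genes, members_in)
        peaks.append(peak)
    peaks = np.asarray(peaks)
    n_ge = int((peaks >= obs_peak - 1e-12).sum())
    if exhaustive:
        return float(n_ge / len(peaks))  # identity relabeling is among them
    return float((1 + n_ge) / (1 + len(peaks)))


# ---------------------------------------------------------------------------
# campaign
# ---------------------------------------------------------------------------

def gsea_campaign(
    exp1: ExpressionExperiment,
    exp2: ExpressionExperiment,
    collections: Sequence[GeneSetCollection],
    contrasts: Sequence[Contrast],
    alpha: float = 0.05,
    n_perm: int = 999,
    seed: int = 0,
    metric: str = "signal_to_noise",
    mode: str = "gene",
    annotation: pd.DataFrame | None = None,
    probe_ids1: Sequence[str] | None = None,
    probe_ids2: Sequence[str] | None = None,
) -> tuple[list[GseaResult], SetReplicationReport]:
    """Run every (set, contrast, experiment) test in both orientations and
    compile the cross-experiment set-level replication report.

    ``n_tests_total`` counts each set once per contrast (the two one-sided
    orientations probe the two tails of the same comparison). A (set,
    contrast) pair is shared-significant when some orientation reaches
    p <= alpha in both experiments with the same enriched arm. Contrasts
    missing a group in either experiment are skipped with a warning.
    """
    experiments = [("exp1", exp1, probe_ids1), ("exp2", exp2, probe_ids2)]
    run_contrasts = []
    for contrast in contrasts:
        ok = all(
            len(exp.samples_in(contrast.reference)) >= 2
            and len(exp.samples_in(contrast.test)) >= 2
            for _, exp, _ in experiments
        )
        if not ok:
            log.warning("contrast %s missing a group; skipped", contrast.name)
            continue
        run_contrasts.append(contrast)

    results: list[GseaResult] = []
    by_key: dict[tuple, dict] = {}
    for ci, contrast in enumerate(run_contrasts):
        for ei, (exp_name, exp, probes) in enumerate(experiments):
            for oi, oriented in enumerate((contrast, contrast.flipped())):
                ranked = rank_genes(exp, oriented, metric=metric,
                                    annotation=annotation, probe_ids=probes)
                universe = set(ranked.genes.tolist())
                N = len(ranked)
                null_cache: dict[int, np.ndarray] = {}
                for coll in collections:
                    for gs in coll:
                        members_in = set(gs.members) & universe
                        k = len(members_in)
                        if k == 0 or k >= N:
                            continue
                        profile, peak, pos = enrichment_score(ranked, members_in)
                        if mode == "gene":
                            if k not in null_cache:
                                rng = np.random.default_rng(
                                    [seed, ci, ei, oi, k]
                                )
                                null_cache[k] = _null_peaks_gene_mode(N, k, n_perm, rng)
                            null = null_cache[k]
                            p = float((1 + int((null >= peak - 1e-12).sum())) / (1 + n_perm))
                            n_used = n_perm
                        else:
                            p = permutation_pvalue(
                                exp, oriented, members_in, n_perm=n_perm,
                                mode="phenotype",
                                seed=abs(hash((seed, ci, ei, oi, gs.name))) % (2**31),
                                metric=metric, annotation=annotation,
                                probe_ids=probes, ranked=ranked,
                            )
                            n_used = n_perm
                        res = GseaResult(
                            set_name=gs.name,
                            contrast=contrast.name,
                            experiment=exp_name,
                            database=coll.database,
                            size_in_universe=k,
                            es_peak=peak,
                            peak_position=pos,
                            p_value=p,
                            n_permutations=n_used,
                            enriched_in=oriented.ref_label,
                            leading_edge=leading_edge(ranked, members_in, pos),
                        )
                        results.append(res)
                        by_key.setdefault((gs.name, contrast.name, oriented.ref_label), {})[
                            exp_name
                        ] = res

    n_sets_total = sum(len(c) for c in collections)
    n_tests_total = reports.gsea_test_count(
        [len(c) for c in collections], len(run_contrasts)
    )
    shared = []
    seen = set()
    for (set_name, contrast_name, side), per_exp in sorted(by_key.items()):
        if len(per_exp) == 2 and all(r.p_value <= alpha for r in per_exp.values()):
            if (set_name, contrast_name) not in seen:
                seen.add((set_name, contrast_name))
                shared.append((set_name, contrast_name, side))
    report = SetReplicationReport(
        n_tests_total=n_tests_total,
        alpha=alpha,
        n_shared_observed=len(shared),
        shared_sets=shared,
    )
    return results, report


def results_table(results: Sequence[GseaResult]) -> pd.DataFrame:
    """Flatten campaign results to a tidy frame (one row per test)."""
    return pd.DataFrame(
        [
            {
                "set_name": r.set_name,
                "contrast": r.contrast,
                "experiment": r.experiment,
                "database": r.database,
                "size": r.size_in_universe,
                "es_peak": r.es_peak,
                "peak_position": r.peak_position,
                "p_value": r.p_value,
                "enriched_in": r.enriched_in,
                "leading_edge": ";".join(r.leading_edge),
            }
            for r in results
        ]
    )
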