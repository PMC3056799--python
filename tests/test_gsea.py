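import numpy as np
import pandas as pd
import pytest

import replicaseq as rs
from replicaseq import reports
from replicaseq.differential import CONTRASTS, get_contrast, welch_test
from replicaseq.errors import StatisticsError
from replicaseq.filtering import present_filter
from replicaseq.gsea import (
    RankedList,
    SetReplicationReport,
    _null_peaks_gene_mode,
    enrichment_score,
    gsea_campaign,
    leading_edge,
    permutation_pvalue,
    rank_genes,
)
from .conftest import make_experiment


def brute_force_es(genes, members):
    """Independent running-sum enumeration: walk every rank explicitly."""
    members = set(members)
    k = sum(g in members for g in genes)
    N = len(genes)
    total, profile = 0.0, []
    for g in genes:
        total += 1.0 / k if g in members else -1.0 / (N - k)
        profile.append(total)
    peak = max(profile)
    return profile, peak, profile.index(peak) + 1


class TestEnrichmentScore:
    def test_ten_gene_universe_ranks_1_2_5(self):
        genes = [f"g{i}" for i in range(1, 11)]
        members = {"g1", "g2", "g5"}
        profile, peak, pos = enrichment_score(genes, members)
        oprofile, opeak, opos = brute_force_es(genes, members)
        np.testing.assert_allclose(profile, oprofile, atol=1e-12)
        assert peak == pytest.approx(opeak) == pytest.approx(5 / 7)
        assert pos == opos == 5
        ranked = RankedList("c", np.array(genes), np.arange(10, 0, -1.0))
        assert set(leading_edge(ranked, members, pos)) == members

    @pytest.mark.parametrize("k", [1, 3, 10])
    def test_perfect_enrichment_peaks_at_one(self, k):
        genes = [f"g{i}" for i in range(50)]
        members = set(genes[:k])
        _, peak, pos = enrichment_score(genes, members)
        assert peak == pytest.approx(1.0)
        assert pos == k

    def test_bottom_set_scores_below_top_set(self):
        genes = [f"g{i}" for i in range(100)]
        _, top_peak, _ = enrichment_score(genes, set(genes[:10]))
        _, bottom_peak, _ = enrichment_score(genes, set(genes[-10:]))
        assert bottom_peak < top_peak
        assert bottom_peak <= 1 / 90 + 1e-12  # never climbs above one miss step

    def test_profile_telescopes_to_zero(self):
        rng = np.random.default_rng(1)
        genes = [f"g{i}" for i in range(200)]
        members = set(rng.choice(genes, size=23, replace=False))
        profile, _, _ = enrichment_score(genes, members)
        assert abs(profile[-1]) < 1e-9

    def test_peak_invariant_to_shuffling_tail_nonmembers(self):
        rng = np.random.default_rng(2)
        genes = [f"g{i}" for i in range(60)]
        members = set(genes[5:20:3])
        _, peak, pos = enrichment_score(genes, members)
        last_member_rank = max(i for i, g in enumerate(genes) if g in members)
        tail = genes[last_member_rank + 1:]
        rng.shuffle(tail)
        shuffled = genes[: last_member_rank + 1] + tail
        _, peak2, pos2 = enrichment_score(shuffled, members)
        assert peak2 == pytest.approx(peak)
        assert pos2 == pos

    def test_members_outside_universe_dropped_with_warning(self, caplog):
        genes = [f"g{i}" for i in range(10)]
        with caplog.at_level("WARNING"):
            _, peak, _ = enrichment_score(genes, {"g1", "nope"})
        assert "absent from the ranked universe" in caplog.text
        assert 0 < peak <= 1

    def test_no_members_in_universe(self):
        with pytest.raises(StatisticsError, match="no set members"):
            enrichment_score(["g1", "g2", "g3"], {"zz"})


RANK_GROUPS = {
    "c1": "CONTROL", "c2": "CONTROL", "c3": "CONTROL", "c4": "CONTROL",
    "a1": "ALC_NTC", "a2": "ALC_NTC", "a3": "ALC_NTO", "a4": "ALC_NTO",
}


def _rank_experiment(seed=0, n=40):
    rng = np.random.default_rng(seed)
    log2 = rng.normal(7, 1, size=(n, 8))
    log2[0, :4] += 3.0   # strongly control-high
    log2[1, 4:] += 3.0   # strongly alcohol-high
    calls = ["P" * 8] * n
    return make_experiment(log2, calls, RANK_GROUPS)


class TestRankGenes:
    def test_control_high_gene_ranks_first(self):
        exp = _rank_experiment()
        ranked = rank_genes(exp, get_contrast("CTRL_vs_ALC"))
        assert ranked.genes[0] == "p000_at"
        assert ranked.genes[-1] == "p001_at"
        assert list(ranked.scores) == sorted(ranked.scores, reverse=True)

    def test_flipping_orientation_reverses_ranking(self):
        exp = _rank_experiment(seed=3)
        c = get_contrast("CTRL_vs_ALC")
        fwd = rank_genes(exp, c)
        rev = rank_genes(exp, c.flipped())
        assert list(fwd.genes) == list(rev.genes[::-1])
        np.testing.assert_allclose(fwd.scores, -rev.scores[::-1], atol=1e-12)

    def test_welch_metric_matches_independent_welch(self):
        exp = _rank_experiment(seed=4)
        ranked = rank_genes(exp, get_contrast("CTRL_vs_ALC"), metric="welch_t")
        log2 = np.log2(exp.signal)
        ctrl = exp.samples_in({"CONTROL"})
        alc = exp.samples_in({"ALC_NTC", "ALC_NTO"})
        expected = {}
        for probe in exp.probe_ids:
            t, _, _ = welch_test(log2.loc[probe, ctrl], log2.loc[probe, alc])
            expected[probe] = t
        order = sorted(expected, key=lambda g: (-expected[g], g))
        assert list(ranked.genes) == order

    def test_probes_collapse_to_genes_by_max_abs_metric(self):
        exp = _rank_experiment(seed=5, n=6)
        annotation = pd.DataFrame(
            {
                "gene_symbol": ["GA", "GA", "GB", "GB", "GC", "GC"],
                "on_platform_A": [True] * 6,
            },
            index=exp.probe_ids,
        )
        ranked = rank_genes(exp, get_contrast("CTRL_vs_ALC"), annotation=annotation)
        assert sorted(ranked.genes) == ["GA", "GB", "GC"]
        assert ranked.genes[0] == "GA"  # carries the planted control-high probe


class TestPermutationPvalue:
    def test_lower_bound_attained_for_planted_set(self):
        rng = np.random.default_rng(6)
        n = 1000
        log2 = rng.normal(7, 0.3, size=(n, 8))
        log2[:20, :4] += 2.0  # top 20 strongly control-high
        exp = make_experiment(log2, ["P" * 8] * n, RANK_GROUPS)
        members = {f"p{i:03d}_at" for i in range(20)}
        p = permutation_pvalue(exp, get_contrast("CTRL_vs_ALC"), members,
                               n_perm=999, mode="gene", seed=1)
        assert p == pytest.approx(1 / 1000)

    def test_p_never_below_lower_bound(self):
        rng = np.random.default_rng(7)
        null = _null_peaks_gene_mode(500, 12, 200, rng)
        # even an observed peak above every permuted one gives (1+0)/(1+n)
        p = (1 + int((null >= 2.0).sum())) / (1 + 200)
        assert p == 1 / 201

    def test_gene_mode_calibration(self):
        """Random member sets under null data give p uniform on its grid:
        P(p <= 0.05) ~ 0.05."""
        rng = np.random.default_rng(8)
        N, k, n_perm, n_draws = 2000, 20, 199, 400
        genes = [f"g{i}" for i in range(N)]
        hits = 0
        null_rng = np.random.default_rng(9)
        for _ in range(n_draws):
            obs = _null_peaks_gene_mode(N, k, 1, rng)[0]
            null = _null_peaks_gene_mode(N, k, n_perm, null_rng)
            p = (1 + int((null >= obs - 1e-12).sum())) / (1 + n_perm)
            hits += p <= 0.05
        rate = hits / n_draws
        sd = np.sqrt(0.05 * 0.95 / n_draws)
        assert abs(rate - 0.05) <= 3 * sd

    def test_phenotype_mode_enumerates_small_designs(self):
        rng = np.random.default_rng(10)
        n = 80
        log2 = rng.normal(7, 0.3, size=(n, 8))
        log2[:10, :4] += 3.0
        exp = make_experiment(log2, ["P" * 8] * n, RANK_GROUPS)
        members = {f"p{i:03d}_at" for i in range(10)}
        p = permutation_pvalue(exp, get_contrast("CTRL_vs_ALC"), members,
                               n_perm=500, mode="phenotype", seed=2)
        # C(8,4) = 70 distinct relabelings, identity included: best p = 1/70
        assert p == pytest.approx(1 / 70)


class TestCampaignArithmetic:
    def test_study_scale_test_count_and_fdr(self):
        """4 contrasts x (415 + 191) sets = 2424 tests; expected chance
        overlap 2424 * 0.00125 ~ 3; 15 observed -> FDR 20%."""
        assert reports.gsea_test_count([415, 191], 4) == 2424
        report = SetReplicationReport(
            n_tests_total=2424, alpha=0.05, n_shared_observed=15,
            shared_sets=[("s", "c", "CONTROL")] * 15,
        )
        assert report.expected_shared == pytest.approx(3.03)
        assert report.expected_shared_display == 3
        assert report.fdr_display == pytest.approx(0.2, rel=1e-12)  # 3/15 = 20%
        assert report.fdr == pytest.approx(3.03 / 15)
        assert reports.round_display(2424 * 0.00125) == 3

    def test_campaign_recovers_planted_sets(self, small_config):
        exp1, exp2, truth = rs.simulate_experiment_pair(small_config)
        f1, f2 = present_filter(exp1), present_filter(exp2)
        results, report = gsea_campaign(
            exp1, exp2, [truth.gene_sets], list(CONTRASTS.values()),
            alpha=0.05, n_perm=199, seed=3, annotation=truth.annotation,
            probe_ids1=f1.retained_probe_ids, probe_ids2=f2.retained_probe_ids,
        )
        assert report.n_tests_total == 4 * len(truth.gene_sets)
        shared_names = {name for name, _, _ in report.shared_sets}
        for planted in truth.planted_enriched_set_names:
            assert planted in shared_names
        # planted sets are enriched on the control side for CTRL_vs_ALC
        sides = {
            (name, contrast): side for name, contrast, side in report.shared_sets
        }
        for planted in truth.planted_enriched_set_names:
            if (planted, "CTRL_vs_ALC") in sides:
                assert sides[(planted, "CTRL_vs_ALC")] == "CONTROL"

    def test_campaign_skips_missing_subgroup_contrast(self, small_config):
        exp1, exp2, truth = rs.simulate_experiment_pair(small_config)
        exp1.groups[exp1.groups == "ALC_NTO"] = "ALC_NTC"
        results, report = gsea_campaign(
            exp1, exp2, [truth.gene_sets],
            [get_contrast("CTRL_vs_ALC"), get_contrast("NTC_vs_NTO")],
            alpha=0.05, n_perm=199, seed=4, annotation=truth.annotation,
        )
        contrasts_run = {r.contrast for r in results}
        assert contrasts_run == {"CTRL_vs_ALC"}
        assert report.n_tests_total == 1 * len(truth.gene_sets)
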