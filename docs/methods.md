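# Methods

## The replication design

`replicaseq` analyses a pair of independent expression experiments run on
nested array platforms: experiment 1 on a smaller platform (probe-set ids a
strict subset of platform 2's), experiment 2 on the full platform with an
extra treated subgroup split. Samples belong to one of three arms —
CONTROL, ALC_NTC and ALC_NTO (treated with closed vs open neural tube in
the embryo-culture design this models); "treated combined" is always
derived as NTC ∪ NTO, never stored.

With 2–4 arrays per arm, familywise or BH correction within one experiment
leaves essentially no discoveries. The design instead tests each
experiment at a relaxed per-gene threshold α and demands *directional
replication*: probe sets significant in both experiments with the same
sign of change. Two independent experiments agree by chance with
probability α₁α₂, and agree in direction with half of that, so

- joint null probability: `p_joint = α₁ · α₂ / 2`,
- expected chance overlap: `n_common · p_joint` over the commonly tested
  universe (present-filtered in both experiments, restricted to the shared
  platform),
- replication FDR: expected / observed (reported as undefined, not 0, when
  nothing replicates).

The same arithmetic is reused at the gene-set level, with
`n_tests = n_contrasts × n_sets` and expected shared sets
`n_tests · α² / 2`. For display the expectation is rounded to the nearest
integer before the quotient (an expectation of 3.03 against 15 observed is
quoted as 3/15 = 20%); JSON reports carry both the raw and the display
values.

## Stage-by-stage choices

**Present filter.** A probe set is analysable if the MAS5 detection call is
"P" on at least half of the arrays of at least one condition (default
conditions: the control arm and the pooled treated arm; per-subgroup
conditions by flag). "At least half" of an odd n means ceil(n/2) — the
strictest reading — with floor(n/2) available for sensitivity analysis.
"M" (marginal) counts as not-present throughout. The filter runs once, on
the default conditions, before any contrast is tested.

**Welch differential expression.** Signals are log₂-transformed with a
floor of 1.0 (MAS5 signals can sit near zero; the floor leaves typical
signals untouched). The statistic is Welch's unequal-variance t with
Welch–Satterthwaite degrees of freedom, two-sided; groups need n ≥ 2. Two
equal constant groups give t = 0, p = 1; p is clamped into (0, 1]. The df
expression is clipped into its mathematical range [min(n)−1, n₁+n₂−2],
which only repairs floating-point underflow at extreme variance ratios.
Fold change is the antilog of the difference of group mean log₂ signals (a
geometric-mean ratio), mapped to the signed convention (ratio 0.5 → −2.0);
an exactly-zero shift maps to +1. A probe's direction (up/down in the test
arm) is assigned only when p ≤ α. No per-experiment multiplicity
correction is applied — the cross-experiment intersection is the error
control.

A caveat the calibration tests reflect: at n = 4 vs 4 Welch's test is
conservative — its true size at nominal 0.05 is ≈ 0.041 under normality
(the Satterthwaite df approximation costs power at tiny n). The analytic
p_joint takes α at face value, so the *empirical* null directional
replication rate sits near 0.041²/2 ≈ 0.00084 rather than 0.00125; the
analytic value remains the design's stated null and the acceptance
calibration verifies agreement within 3 binomial SDs at the single-pair
problem size (~13,000 tested probes), where both are compatible. For the
same reason, the ≥90%-recovery regime for planted effects begins at
roughly 4× the array noise SD at these group sizes, not at the asymptotic
3×.

**On/off calls.** `off_in_test` needs Present on ≥ ceil(n/2) reference
arrays *and zero* Present calls across all test-arm arrays (`on_in_test`
mirrored). Both thresholds are configurable. The attached p-value defaults
to the Welch p of the same contrast; a Fisher-exact mode on the P/A counts
is provided because presence-based p-values are a defensible alternative
when the quantitative signal is at noise level.

**GSEA.** Genes are ranked by association with the contrast — default
signal-to-noise (Δmean / (sd₁+sd₂) of log₂ signals), Welch t by flag —
oriented so positive means higher in the reference arm; probes collapse to
genes by maximum absolute metric; ties break lexicographically by gene id
so rankings are deterministic. The enrichment score is the classic
*unweighted* Kolmogorov–Smirnov running sum (hit +1/n_hits, miss
−1/(N−n_hits)); the weighted 2005-style variant is deliberately out of
scope of the default because the unweighted cumulative-rank form is the
model implemented here. The statistic is the profile maximum (one-sided,
top-enrichment only); the opposite tail is probed by flipping the contrast
orientation, and campaigns run both orientations. The leading edge is the
member genes at ranks up to (and including) the ES peak.

Significance is by permutation: p = (1 + #{perm peak ≥ observed}) /
(1 + n_perm), bounded below by 1/(n_perm+1). The default mode draws random
member sets of equal size from the ranked universe (n_perm = 999), because
phenotype relabeling is degenerate at these group sizes — 4-vs-4 has only
C(8,4) = 70 distinct relabelings. Phenotype mode is available and
enumerates all distinct relabelings exhaustively when they number fewer
than n_perm (the identity labeling included, p = #{≥ obs}/n_distinct).
Null peak distributions are cached per set size within a (contrast,
experiment, orientation), and every permutation stream is seeded from the
campaign seed plus its coordinates, so reruns are byte-identical.

Set-level replication counts each set once per contrast; a (set, contrast)
pair is shared when some orientation reaches p ≤ α in both experiments
with the same enriched arm. Contrasts missing a subgroup in either
experiment are skipped with a warning and excluded from the test count.

**Clustering.** Arrays are compared by 1 − Pearson correlation of log₂
profiles over the present-filtered universe (the standard choice for
arrays; Euclidean by flag) and agglomerated by average linkage (UPGMA).
Samples are canonicalised by id before linkage, so the tree is invariant
to input order; a constant profile raises an error naming the sample.
Trees serialise to Newick with branch lengths; cutting removes the k−1
highest merges.

**qPCR.** ΔΔCt: replicate Cts average within a sample, ΔCt = Ct_target −
Ct_reference per sample, group ΔΔCt = mean treated ΔCt − mean control ΔCt,
relative quantity 2^−ΔΔCt. Aggregation is by arithmetic mean of per-sample
ΔCt (per-replicate propagation is possible by passing replicate-level rows
as samples). ΔΔCt is invariant to a per-sample machine offset since the
offset cancels in ΔCt. The standard-curve method fits Ct = a·log₁₀(amount)
+ b by least squares over ≥ 3 points spanning ≥ 2 decades, inverts it for
unknowns, and reports slope, R² and the amplification efficiency
10^(−1/a) − 1 as QC (a perfect doubling has a = −3.32, efficiency 1).
Group comparison is one-way ANOVA followed by pairwise pooled-variance
Student t tests; all-identical groups are reported as p = 1 (no evidence
of difference) rather than NaN.

## The synthetic-data generator

The generator emulates the statistical structure the pipeline assumes and
nothing more. Per probe, a baseline log₂ signal ~ N(7.0, 1.5²) shared by
both experiments; per array, i.i.d. N(0, 0.25²) noise; signals are stored
on the natural scale (2^log₂) to mirror MAS5 output and re-logged by the
statistics. A detection call is "P" iff the log₂ signal exceeds 6.5, then
flipped symmetrically with probability 0.02 — with these values ~63–67% of
probes pass the present filter, matching the regime of real MAS5 data on
embryonic samples. The generator never emits "M"; readers accept it.

Planted truth (all categories disjoint, all on the shared platform so the
intersection can recover them):

- 150 down- and 150 up-regulated probes at ±2.0 log₂ (4-fold) in the
  treated arms, with the NTC arm expressing 60% of the NTO effect
  (`subgroup_effect_ratio`) — one shared per-probe effect across both
  experiments. The subgroup ratio is what makes the three arms separable
  by clustering; a single uniform treated effect would make NTC and NTO
  statistically identical.
- 3 of 30 gene sets (sizes 10–40) coherently shifted down by 0.75 log₂ in
  treated arms; non-planted sets draw members only from zero-effect probes
  so that only planted sets are truly coherent.
- 20 "off" probes forced Present on every control array and Absent on
  every treated array (exempt from call-flip noise, since they model
  transcription switched off rather than detection noise).

Differential and set effects are planted only on probes whose baseline
clears the detection threshold by 2 noise SDs: an expression change is
observable only on a detectably expressed transcript, and planting on
sub-threshold probes would silently remove part of the truth at the filter
stage. Defaults were fixed by a priori power analysis so that the planted
effects are recoverable at the study's group sizes (joint two-experiment
power ≳ 0.97 for the 4-fold effects).

What the generator does **not** model — and hence what passing tests do
not establish about real arrays: probe-level (PM/MM) intensities and MAS5
condensation itself, normalisation artefacts, batch or litter effects,
correlated noise across probes, heavy-tailed biological variance,
between-experiment effect heterogeneity, and annotation ambiguity
(probe→gene is 1:1 in simulation). Calibration and recovery results
transfer to real data only insofar as log-normal signal plus independent
per-array noise is adequate.

All randomness flows from a single integer seed through
`numpy.random.default_rng`; identical configuration and seed give
bit-identical matrices, calls, ground truth and pipeline outputs.

## Problem sizes used in the checks

The test suite exercises the full default design (20,000 / 13,810 probes,
4/2/2 and 4/3/4 arms) for calibration and recovery, and scaled-down
designs (1,200–2,000 probes, 5–8 gene sets, 199 permutations) for
pipeline and CLI round-trips. `scripts/acceptance.py` pools five null
pairs of 20,000 shared probes (~65,000 tested probe sets) for the
empirical null replication fraction. The set-count arithmetic of a
606-set, 4-contrast campaign (2424 tests) is verified analytically and
with a constructed 415 + 191-set GMT fixture rather than by simulating a
campaign of that width.

## Known limitations

- The analytic FDR assumes the per-experiment tests have exact size α and
  independent experiments; the Welch small-n conservativeness above makes
  it mildly anti-conservative as an FDR denominator (expected overlap
  overstated, FDR overstated — a safe direction).
- Gene-mode permutation tests the "competitive" null (random gene sets),
  not the self-contained phenotype null; at these group sizes that is the
  only non-degenerate default, but it is insensitive to correlated
  inter-gene structure.
- On/off calling with 2–4 reference arrays has limited evidential value
  per probe; it is a screen, not a test, which is why both Welch and
  Fisher p-values are offered as annotations.
- Fold-change estimation from log-mean differences (geometric means) can
  differ from ratio-of-arithmetic-means estimates on skewed signals; the
  choice is documented and deliberate.
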