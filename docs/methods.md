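# Methods

This note documents the models, parameter choices and numerical conventions
behind `mirddr`, and what the synthetic validation does and does not
demonstrate.

## Quantification model

Reads are matched to the mature reference at 100% sequence identity. This is
a deliberate simplification of aligner-based workflows: the genome-mapping
step in such workflows acts only as a pre-filter before exact matching to
mature sequences, so the package matches directly to the mature reference.
Consequences: sequencing errors and isomiRs (3′-end variants) are not
counted, and reads matching several identical mature entries (e.g.
miR-365a/b-3p) increment *all* of them and are flagged ambiguous — the
redundancy-resolution step downstream collapses such groups. `N` bases never
match, so exactness is preserved.

Adapter trimming is left-most exact match, falling back to a terminal
read-suffix/adapter-prefix overlap of ≥ `min_overlap` (default 6) bases.
"Low complexity (polyN)" is operationalized as a mono-nucleotide fraction
> 0.8 *or* a homopolymer run ≥ 15 nt: this removes poly(A)/poly(N) artifacts
while keeping genuinely AU-rich miRNAs. Rejections are attributed to the
first failing rule, length before complexity.

## Differential expression

The data have technical replicates only (repeated library preparation from
one RNA sample), so no biological-variance model is fitted. Each comparison
(cell line, time t vs 0 h) treats the merged raw counts against the merged
library sizes as a 2×2 table:

* `exact_fisher` (default): two-sided Fisher's exact test, i.e. the sum of
  hypergeometric point probabilities not exceeding that of the observed
  table (delegated to `scipy.stats.fisher_exact`, cross-checked in the
  test-suite against a direct enumeration oracle to 1e-12);
* `binomial_approx`: x_treat ~ Binomial(x_treat + x_ctrl,
  lib_treat/(lib_treat+lib_ctrl)), two-sided — the classical approximation
  for deep libraries (observed agreement with the exact test at lib = 10⁶:
  |Δp| < 1e-3).

Normalization order is fixed: (1) zero cells ← pseudocount 1; (2) drop
miRNAs whose aggregate **raw** count over all samples is < 100 (strict);
(3) scale each column so its total equals the mean raw library size. The
scale target preserves the printed equivalence A ≥ 5 ⇔ ~32 reads. Tests run
on raw integers; M and A are computed on normalized values. Correction is
Bonferroni over the miRNAs tested, per comparison (the study counted "the
total number of miRNA tested"); whether correction should span comparisons
jointly is ambiguous — per-comparison was chosen and is recorded in the
output metadata. Significance is inclusive on the M and A boundaries and
strict on alpha.

## DDR selection

The robustness filter implements the three published criteria with "similar
trend" read as *same sign of M at 4 h and 24 h* (an exactly zero M fails).
Criterion 3 (support in ≥ 2 cell lines and/or ≥ 2 replicates) takes
replicate support from per-replicate comparisons of each replicate against
its own control.

Kinetic clusters are assigned by a deterministic rule rather than
hierarchical clustering: direction = sign of M at the time of max |M|,
peak = that time; |M| ties go to 24 h (late induction dominates the data
this rule summarizes). The label conventions differ between published
figures, so the (direction, peak) → {A–D} mapping is a preset
(`mcf10a`: A = early induced; `hct116`: A = late induced), never hard-coded.

p53 dependence has no published numeric rule; the package calls
`p53_dependent` iff significant in WT while the TP53⁻/⁻ record is neither
significant nor shows a residual effect (max |M_KO| < m_thresh/2, i.e.
0.375 by default), `p53_independent` iff the knockout stays significant
with the same sign, and `indeterminate` otherwise (missing KO data, WT not
significant, or partial attenuation). The threshold is configurable.

## Genomic context

Intragenic = fully contained in a same-strand annotated transcript; nested
transcripts resolve to the smallest containing span (host gene).
Clustering is single-linkage chaining with inter-locus gap < 10 kb (strict,
measured between stem-loop interval ends, strand-agnostic). Loci without
annotation are reported "unassigned" and excluded from the contingency
tables, mirroring the smaller category denominators such data produce.
Category enrichment uses the same exact count test as differential
expression. A published p-value for the intragenic-clustered category is not
reproduced by a standard two-sided exact test on the printed counts (the
oracle gives a smaller p); the operation therefore computes and reports, but
the test-suite asserts only against the enumeration oracle.

## Motif ranking

PWMs are probability matrices with 0.01 probability mass added per cell;
the seven curated p53 matrices used in the original analysis are licensed
config entries, not shipped data — simulations and tests use synthetic
p53-like matrices (`demo_pwms`, labelled synthetic). Scanning is log2-odds
against a 0-order background estimated from the scanned region set
(pseudocount 0.01, configurable).

Homotypic CRM scoring: within each sliding window (500 bp, stride
window/2), the maximum-weight subset of non-overlapping motif hits with
log2-odds > 0 (any PWM, either strand) is summed by weighted-interval-
scheduling dynamic programming; the region score is the max over windows,
floored at 0 so every region scores ("cluster threshold zero" semantics).
The DP is exact — it always equals an exhaustive hit-subset search, unlike
a greedy pick which can lose on adversarial overlaps — and is a documented
approximation of the hidden-state CRM model of dedicated scanners.
Intragenic miRNAs contribute two candidate regions (host TSS and intragenic
anchor); the feature score is the max over its regions. Orthologous regions
per species are inputs; liftover is out of scope.

Cross-species aggregation: per species, features are ranked by score
descending (average ranks on ties), normalized to r ∈ (0,1]; a missing
species contributes r = 1. The raw aggregate is the exact joint cumulative
probability that n uniform order statistics fall at or below the sorted
observed ranks, computed by the stable V-recursion (exact in double
precision for n ≤ 20; for n = 1 it reduces to q = r). This joint probability
is *conservative* — under the null it concentrates near 0 as n grows — so
`aggregate_ranking` by default passes it through its own null distribution
(a probability-integral transform against a seeded 100,000-draw null table,
cached per n). The calibrated q is uniform under the null and the transform
is monotone, so rankings are unchanged; both `raw_q` and calibrated `q` are
reported, with final_score = −ln(q) (natural log; the base only rescales).
Final-ranking ties break lexicographically by feature id.

## Preranked GSEA

Weighted running statistic with p = 1: a hit at rank i adds
|s_i|/Σ_set|s|, a miss subtracts 1/(N − N_hits); ES is the running value
furthest from 0 (earliest position on ties, which fixes the leading edge
deterministically); core enrichment = members at or before a positive peak.
The permutation null draws n_perm random same-size sets from the ranked ids
(gene-set permutation; seeded, bit-reproducible). NES divides ES by the
mean same-sign null ES ("mean div"); nominal p is the same-sign null tail;
FDR q follows the standard pooled positive/negative procedure, clipped to 1.
Rank-metric scores are consumed as given — the motif final_score is not
re-transformed.

## Synthetic data generator

The generator emulates the study design: 3 cell lines (one TP53-null) ×
{0, 4, 24} h × 2 technical replicates, defaulting to 300 miRNAs, library
size 150,000 ± 10% (CV), and 10 pseudo-species promoter panels. Baselines
are log-normal (median ≈ 50 counts, σ = 1.3 in ln-space). Counts per
condition are one negative-binomial biological draw (gamma–Poisson;
var = m + φm², default φ = 0.005, configurable to 0 for Poisson closed-form
checks), split between technical replicates by binomial thinning — so
replicates share biological noise exactly as repeated library preparations
from one RNA sample do. The small default dispersion reflects that
technical replicates carry little overdispersion; the exact count test
assumes as much, and the null-calibration test measures the consequence.

Spikes follow four archetypes — induced/repressed × early/late peak — with
peak effect 2.0 log2 (4-fold) and 0.4× the peak effect at the other time
point (same sign, so trend filters see consistent direction). Spike
baselines are clipped at the 40th percentile of the abundance distribution
(strongly regulated species of interest are well-expressed ones). 75% of
induced and 25% of repressed spikes are flagged p53-dependent; the
TP53-null line zeroes the flagged effects. The reference deliberately
contains two stem-loops contributing both arms (3p baseline = 0.2× its 5p
sibling, the realistic star-arm asymmetry) and two id pairs with identical
mature sequences, so the redundancy rules are exercised; motif plants go to
the functional representative of each redundant group (arms of one
stem-loop share a promoter).

Annotations place loci on one pseudo-chromosome with intra-cluster gaps
drawn in [200, 9000) bp and inter-unit gaps ≥ 12 kb; intragenic units sit
strictly inside same-strand transcripts, and every third intergenic single
receives an opposite-strand covering transcript as a strand-rule decoy.
Promoters are i.i.d. backgrounds at GC 0.41 with consensus-sampled sites
(temperature 0.5) planted non-overlapping in 6 of 10 species by default.

What the generator does **not** emulate: sequencing error, GC bias,
isomiRs, biological replicate variance, cell-type-specific archetype
composition, and real promoter sequence structure (CpG islands, repeats).
Passing tests therefore demonstrate correctness of the pipeline's logic and
calibration under the stated statistical model, not performance on real
libraries. One realistic artifact *is* present: strong induced spikes shift
the compositional total, so null miRNAs acquire small negative M — the same
compositionality that affects library-size-scaled real data.

## Problem sizes and determinism

Default end-to-end runs use 300 miRNAs × 18 samples, 10 species × 1 kb
promoters and 1000 GSEA permutations (≈ 10 s on one core); the
test-suite's property checks use 200–500 features and 20 seeds for the
power/calibration studies. All randomness flows through
`numpy.random.default_rng` from a single seed per run; re-runs are
byte-identical, and the motif-calibration null table uses its own fixed
internal seed so calibrated scores do not depend on the analysis seed.

## Known limitations

* Exact matching undercounts in the presence of sequencing errors; an
  end-tolerance option exists but defaults to strict identity.
* The Fisher/binomial count test is anti-conservative under biological
  overdispersion; with technical replicates only, the published joint
  M/A/p thresholds are the guard, and the package reproduces exactly that
  behaviour rather than fitting a dispersion model (out of scope).
* The CRM scorer approximates hidden-state scanners by windowed best
  non-overlapping hit sums; absolute scores are not comparable to such
  tools, rankings are.
* FDR q-values use the pooled two-sided convention without monotonicity
  enforcement across NES.
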