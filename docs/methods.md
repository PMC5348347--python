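# Methods

This note documents the statistical procedures implemented in `pairomics`,
the defaults and their rationale, and what the synthetic cohorts do and do
not establish. Coordinates are 0-based half-open everywhere internally;
BED files pass through unchanged and SEG-like tables are converted from
1-based inclusive on read/write.

## Copy number

**Winsorization.** Per chromosome, probe log2 ratios are clipped to
median ± k·MAD with k = 2.5 and the MAD scaled by 1.4826 (consistent
estimator of the SD under normality). When the MAD is zero the vector is
returned unchanged: clipping to a zero-width band would erase genuine
signal rather than tame outliers.

**Segmentation.** The profile is segmented by exact minimization of
Σ(xᵢ − μ_segment)² + λ·(number of breakpoints) via an O(n²) dynamic
program. An exact solver was chosen over faster heuristics because it can
be verified against exhaustive enumeration (done in the test suite for
n ≤ 12 at arbitrary λ). Segment bounds span from the first member probe to
one past the last member probe; means are plain arithmetic means. λ is a
config key (demo default 2.0, chosen so the zero-noise fixtures segment
exactly); for very long probe vectors the quadratic cost is the binding
constraint, so keep per-chromosome probe counts in the low thousands or
raise the probe spacing.

**CNA calling.** A segment is called when all of: |mean log2| beyond the
±0.1 thresholds; ≥ 25 markers; ≥ 100 kb; and < 50% of its length covered
by the known-CNV mask. All four are config keys.

**Pair evolution.** Gains and losses are compared separately. A relapse
call is *acquired* when < 50% of its length is covered by the union of
same-state diagnosis calls (symmetrically for *lost*). The 50%
reciprocal-overlap rule is this package's own numeric choice; visual
call-by-call comparison has no canonical threshold.

**Burden.** Per-sample "changed bp" is the length of the *union* of all
called intervals (not the sum, so split or overlapping calls cannot
double-count), thresholded at 100 Mb into small/large classes. Union
rather than gained+lost sum is a documented interpretation choice.

**Counts and recurrence.** Group differences in per-sample
imbalance/gain/loss counts use the two-sided Mann–Whitney U test, exact
when both groups have ≤ 8 tie-free samples, otherwise the tie-corrected
normal approximation. The acquisition-vs-loss contrast is a two-sided
Wilcoxon signed-rank on per-pair (n_acquired − n_lost) — a documented
choice, not a claim about how any published p-value was obtained.
Recurrent acquisition uses a permutation null that preserves each pair's
acquired-lesion lengths but places them uniformly on the genome
(1000 permutations by default), with BH correction across bins; the
add-one p-value estimator keeps p ≥ 1/(B+1).

## Methylation

**Scales.** Methylation lives on two scales: fractions m ∈ [0,1] and
log ratios x = log2(m/(1−m)), a bijection on (0,1). Normalization and
batch correction operate on log ratios; DMR effect sizes are reported in
fraction (percentage-point) units.

**Quantile normalization** forces every column onto the mean-of-sorted-
columns distribution with average ranks for ties.

**Batch correction** is a parametric empirical-Bayes location/scale
adjustment in the ComBat style: probe-standardized data, per-batch
location and scale parameters shrunk toward batch-wide means via
method-of-moments normal/inverse-gamma priors, solved by fixed-point
iteration, then mapped back to the original scale with grand means
preserved. A non-EB per-batch mean-centering fallback covers cohorts with
batches of fewer than two samples.

**Peaks.** The scanner vendor's probe "peak score" is proprietary; the
stand-in is −log10 of the one-sided rank-sum p-value (normal
approximation) of the probes within 750 bp of each probe against the
sample's global distribution, so the conventional cutoff of 2 corresponds
to p < 0.01. A peak is a maximal run of qualifying probes whose
consecutive members lie within 750 bp, with ≥ 2 qualifying probes.
Per-sample "methylated region" counts are counts of disjoint peaks.

**DMRs.** Per-probe mean paired differences (relapse − diagnosis) are
smoothed by a 3-probe running mean inside runs broken at inter-probe gaps
> 1 kb. Candidate regions are maximal same-sign runs with
|smoothed Δ| > 0.05; region *edges are trimmed to probes whose raw |Δ|
also exceeds the cutoff*, so on noiseless data the reported bounds equal
the planted bounds exactly while smoothing still stabilizes noisy
interiors. Regions with < 4 probes are removed; "> 5% average
methylation difference" is read as |mean paired difference| > 0.05 on the
fraction scale. The p-value per region comes from sign-flip permutations
of pair labels (all 2ⁿ flips when n ≤ 10) using the area statistic
|Σ smoothed Δ|, recomputed over the region's probes for each flip. This
is a running-mean approximation, not a loess-based reimplementation of
the CHARM package.

**Promoter windows.** Promoter = 2000 bp upstream of the TSS
(strand-aware: [TSS−2000, TSS) on +, [TSS, TSS+2000) on −); core
promoter = TSS ± 250 bp (strand-symmetric). Gene-level values are the
mean or max over window probes; genes with no probe get a missing value
and are excluded downstream. Region→gene assignment minimizes
midpoint-to-TSS distance, ties broken toward the smaller coordinate.
Before the paired SAM test on promoter methylation, the 50% of genes with
lower profile variance are removed.

## Expression

**Filters.** Low-expression: a gene is kept when it exceeds the floor
(default: global 25th percentile) in ≥ 25% of samples — the published
workflow states the filter without numbers, so these defaults are
implementation choices. Variance filter: the lower-variance fraction
(default 50%) is dropped, ties broken by gene id.

**SAM two-class paired.** Per gene, zᵢ = relapse − diagnosis per pair,
d = z̄/(s + s₀) with s = sd(z)/√n. The fudge factor s₀ is chosen on the
{0,5,…,100} percentile grid of s to minimize the coefficient of variation
of the median |d| across s-quantile bins (Tusher-style). The null is all
2ⁿ sign flips when n ≤ 10, else 1000 random flips. The q-value at
threshold |d_g| is (median null exceedance count)/(observed exceedance
count), clipped to [0,1] and monotonized so q never decreases as |d|
decreases. π₀ estimation is omitted — the estimator is conservative —
and fold changes are carried on the log2 scale ("≥ 2-fold" means
|log2 FC| ≥ 1).

**Unsupervised.** UPGMA (group-average, Euclidean) via the standard
linkage algorithm with deterministic tie handling; flat clusters by
height cut (the cut height is data-scale dependent and therefore a
parameter, not a constant). Classical (Torgerson) MDS on double-centered
squared distances, axis signs fixed by making each component's first
non-zero loading positive.

**Over-representation.** One-sided hypergeometric p per user-supplied
gene set, BH across sets. No live databases are consulted.

## Integration

Gene-level CNA is the probe-weighted mean log2 over the gene span, so
partial overlaps contribute continuously; the per-pair *delta* is the
relapse − diagnosis difference of these means. Candidate genes for the
correlation screens need |expression FC| ≥ 2 (CNA screen) or ≥ 1.5
(methylation screen) in ≥ 3 pairs. Per gene, Pearson r across pairs with
two-sided p and BH-FDR; the headline reporting rule is |r| > 0.8 and
FDR < 0.05, with a positive-sign filter for dosage and a negative-sign
filter for methylation. Zero-variance genes are skipped and flagged.

The DMR × expression screen reports *inverse* associations only:
hypermethylated DMR with ≥ 1.5-fold expression loss in ≥ 3 pairs, or
hypomethylated with the corresponding gain. Burden-stratified
differential expression reruns the paired SAM within each burden class
(strata with < 3 pairs are skipped). The pair-by-pair screen counts pairs
where |expression log2 FC| ≥ 1 co-occurs with a same-gene platform change
(CNA |Δ| ≥ 0.1; methylation |Δ| ≥ 0.05) in the required sign relation.

The region-wise procedure is a deliberately simplified surrogate for
published region-dependent integration methods ("SIM-surrogate", and so
labelled): per region, a pair-level intercept (the across-gene mean of
gene-centred expression FC) is shrunk by the method-of-moments
reliability τ²/(τ² + σ²/G) and removed before per-gene correlation, with
BH-FDR within each region. It removes region-level confounding shifts; it
does not reproduce any published package's estimates.

## Meta-analysis

Hedges' g uses the standard small-sample correction J = 1 − 3/(4·df−1)
and variance (n₁+n₂)/(n₁n₂) + g²/(2(n₁+n₂)). Heterogeneity: Cochran's Q
with fixed-effect weights and a χ²(k−1) p-value; I² = max(0,(Q−df)/Q)·100;
studies are flagged heterogeneous when p(Q) < 0.05 and I² > 50%. Pooling
is DerSimonian–Laird: τ² = max(0,(Q−df)/C), C = Σw − Σw²/Σw, weights
1/(vᵢ+τ²), normal-theory 95% CI (multiplier 1.96; no Knapp–Hartung
adjustment) and z-test. When Q ≤ df the estimate reduces exactly to
fixed-effect inverse-variance pooling. Study summaries computed from
expression matrices treat the groups as independent because pairing is
not shared across studies; paired summaries can be supplied directly.
Gene matching across studies is by identifier only.

## Synthetic cohorts: the stated world

The generator emulates the statistical structure the analyses assume, at
a scaled-down genome (default demo: 4 × 20 Mb chromosomes, ~1/40 of a
human genome; the 100-Mb burden cutoff is scaled to 10 Mb in the demo
config for the same reason — the library default remains 100 Mb).

* **Copy number**: per pair, 2 shared segments (both time points),
  2 private acquired segments (relapse only; the first half of the pairs
  get 4× as many, creating a high-burden subgroup), optional diagnosis-
  only "lost" segments, and 1 recurrent lesion at a fixed location
  acquired by ~50% of pairs at amplification level (|log2| = 1.0, vs
  ±0.5 for private segments). Probe noise N(0, 0.1).
* **Methylation**: Beta(2,2) baselines shared across samples; each DMR
  spans 6 contiguous probes, shifts relapse fractions by ±0.20
  (hypermethylation in ~70% of DMRs) in ~70% of pairs, with promoter-
  targeted placement for designated genes; +0.05 on alternating batches;
  probe noise N(0, 0.03), clipped to [0,1]. Methylation probes are tiled
  densely (400 bp in the demo) because a 2-kb promoter window must
  contain several probes.
* **Expression**: baseline N(7, 1.5²) per gene; + 1.0 × the probe-
  weighted true CNA log2 (dosage); − 3 × the promoter methylation shift
  (so a 0.20 DMR gives a 0.6 log2 ≈ 1.5-fold repression); − 1.0 log2 for
  5 directly relapse-regulated genes; noise N(0, 0.03).

Noise magnitudes of the emulated arrays are not published; these defaults
were chosen — once, by power analysis before the recovery tests were
run — to make planted signal clearly separable, and are config keys.
Pairs default to 17, the expression-cohort size of the emulated design.
The generator does **not** simulate raw scanner intensities, allele-
specific copy number, tumour purity/ploidy, clonal fractions, CpG-island
structure, or probe-specific affinity; a green recovery test therefore
establishes correctness of the statistical machinery on its stated
assumptions, not performance on raw array data.

Determinism: identical (parameters, seed) give byte-identical outputs;
zero-noise settings make every downstream estimate exact and are used as
oracle fixtures throughout the test suite.

## Numerical choices and degenerate inputs

* All-constant paired differences: the SAM denominator is floored at a
  tiny positive value so d stays defined.
* MAD = 0 in winsorization: no-op (documented above).
* Quantile normalization of a single sample: identity with a warning.
* Batch confounded 1:1 with condition: correction would remove the
  signal; the caller is warned by construction of the design (batches are
  assigned per pair, never per time point, in the generator).
* Permutation p-values use the add-one estimator; BH-FDR is used wherever
  a false-discovery rate is reported without a named method.
* Classical MDS clips negative eigenvalues at zero; degenerate
  (equidistant) configurations are handled by the symmetric eigensolver.

## Known limitations

* The segmentation DP is exact but O(n²) per chromosome.
* The CHARM-style DMR caller approximates loess smoothing by a short
  running mean; smoothing span and cutoff quantile of the original are
  not replicated.
* The peak score is a documented stand-in for proprietary scanner output.
* The SIM-surrogate is not the published SIM algorithm.
* AU (multiscale bootstrap) cluster p-values are out of scope.
* No raw CEL/XYS/IDAT parsing, no RMA, no external database access.
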