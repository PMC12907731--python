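# Methods

## The decoding model

Two-dimensional overlapped pooling places each of up to R × C samples in one
row pool and one column pool. Treating each pool's call set as a set of
normalized variant keys, the decoder computes, per axis element, the variants
unique to that element (its calls minus the union of all other pools on the
axis) and assigns the intersection of row-unique and column-unique variants to
the individual at the intersecting cell. Two facts follow directly from the
set algebra and are enforced as tested invariants:

* a variant can be assigned to at most one individual (uniqueness on both
  axes determines at most one cell);
* on noiseless pools the assigned sets are exactly the variants with one
  carrier in the matrix. Variants shared by two or more individuals are never
  assigned — they surface in the `row_only`/`col_only`/`unassigned_shared`
  buckets and require individual follow-up.

A false negative in one of a variant's two pools demotes it from *assigned*
to *row-only* (or *column-only*); it can never migrate to another individual.
A false positive is assigned only when a matching key appears in exactly one
row pool and one column pool, which is why recurrent (systematic) artifacts
are the dangerous class and per-pool random noise is largely harmless to the
decoder.

## Variant identity and normalization

All set operations use `(chrom, pos, ref, alt)` equality. Genotypes are
parsed but never part of identity: pooled call sets are compared on detection
only, since pool genotypes at ploidy 2m are not comparable to diploid calls.
Records are split per alternate allele before keys exist; per-allele
annotation lists follow their allele, scalars are copied. Indels are
canonicalized by the standard trim-and-shift algorithm (iteratively trim the
shared trailing base, re-anchoring with the preceding reference base when an
allele would empty, then trim shared leading bases), which yields the
leftmost parsimonious representation. The implementation is checked in tests
against a brute-force enumeration oracle and against `bcftools norm` on small
fixtures. Symbolic, breakend and spanning-deletion alleles are rejected: the
scope is SNVs and small indels. One consequence of key-exact matching worth
stating: if two gold-standard callers emit different representations of the
same underlying indel, normalization either merges them into one HIGH key or
leaves two LOW keys — no fuzzy haplotype matching is attempted.

## Gold standard and labels

Per individual, HIGH confidence = intersection of two callers' normalized
sets, LOW = symmetric difference. Theoretical pool sets are unions of member
individuals' filtered sets; private variants are those with exactly one
carrier. The confidence filter is a parameter at every call site: validation
baselines conventionally use HIGH only, while filter-training labels use the
union (HIGH ∪ LOW) so that borderline true variants are not taught as
errors. Records with at least one called alternate allele are kept when
reading per-individual VCFs; half calls do not exclude a record. Truth
variants absent from the calls produce no training rows — false negatives are
not observations of the caller's annotation space.

## The simulator

The simulator works at the variant level, not the read level: its purpose is
to exercise the decoder, filter and evaluation machinery end to end at desk
scale, not to reproduce platform error profiles.

* **Cohort.** Allele frequencies are i.i.d. Beta(α = 0.3, β = 8) — a
  rare-skewed spectrum appropriate for a rare-disease panel; genotypes are
  Hardy–Weinberg draws (0/1/2 copies). Population structure and relatedness
  are not modelled.
* **Sites.** SNVs and single-base indels (default 15% indels) are placed on a
  synthetic contig (default 100 kb), constructed so that every site is
  already in canonical left-aligned form (single-base indels never duplicate
  their anchor base); this is asserted by a normalization fixed-point test.
* **Pool depth.** A pool of m diploid individuals has ploidy 2m; site depth
  ~ Poisson(2m·c) for allelic coverage c (so the reference design — pools of
  10 at c = 100 — gives ~2000× pool depth). Alt reads ~ Binomial(depth, p)
  with p = (ac/2m)(1−e) + (1−ac/2m)(e/3) for summed copies ac and per-base
  error e = 0.001. A call is emitted when alt reads ≥ 3 and alt fraction
  ≥ 0.01.
* **Indel detection deficit.** Real indel failures are dominated by alignment
  in low-complexity regions, upstream of any depth model. They are emulated
  by an explicit per-pool miss probability that grows with pool size,
  q(m) = 0.03 + 0.008·(m − 1), chosen so that indel assignment sensitivity
  degrades from roughly 0.9 at 2 × 2 to roughly 0.6 at 24 × 24 while SNV
  sensitivity stays near 1 — the qualitative behaviour expected of this
  design. This is a modelling device, not a mechanistic model.
* **Artifacts.** Each pool receives Poisson(30) artifact calls at positions
  drawn uniformly from the contig (SNV/indel mix matching `indel_fraction`).
  The contig length controls how often the same artifact recurs in a row and
  a column pool and is therefore falsely assignable; 100 kb gives of order
  one collision per 10 × 10 matrix.
* **Annotations.** Every emitted call carries synthetic technical annotations
  drawn from class-conditional gamma/normal families (see
  `simulate.ANNOTATION_MODEL`): true calls mimic clean germline calls (QD
  ~ Γ(12, 1.5), MQ ≈ 60, low FS/SOR, centred rank sums), artifacts are
  shifted toward low QD, high strand bias and negative rank sums; rank-sum
  annotations are missing at rate 0.1. The two classes are well separated by
  construction, so classifiers reach near-perfect out-of-fold AUROC on
  simulated tables. Passing the end-to-end filtering tests therefore shows
  the machinery is correct — labeling, nested CV, calibration, routing — not
  that real pooled data is this easy; real annotation distributions overlap
  far more, and indel labels in particular are noisier.

Everything is bit-reproducible from the config seed; grid sweeps derive child
seeds from a seed sequence over (size, coverage, replicate).

## Filter training and calibration

One classifier per variant type. The pipeline default is logistic regression
for SNVs and random forest for indels; gradient boosting (with
`scale_pos_weight` from the class balance) and a supervised Gaussian-mixture
classifier (one mixture per class, Bayes rule with equal priors) are
available for benchmarking. Missing features are imputed with the training
median inside the fitted pipeline; LR and the GMM are standardized. Class
imbalance is handled by class weighting, not resampling, to keep predicted
probabilities interpretable for threshold calibration.

Nested cross-validation uses stratified folds: 5 repetitions × 10 outer
folds, hyperparameters chosen by a 5-fold inner grid search (scoring F1;
small documented grids — LR: C ∈ {0.01, 0.1, 1, 10}; RF: max depth ∈
{∞, 8}; XGB: depth ∈ {3, 6} × learning rate ∈ {0.1, 0.3}; GMM: components ∈
{1, 2, 4}). Out-of-fold probabilities are recorded for every row in every
repetition (50 outer models per run). The final model is refit on the full
table with hyperparameters chosen by a fresh inner-CV grid search on all
rows; the alternative (majority vote over outer winners) gives the same
choice on all tables we generate, and a single rule is easier to reason
about. If the minority class has fewer rows than outer folds the fit fails
with an explicit message rather than silently de-stratifying.

Thresholds are calibrated on the out-of-fold probabilities: candidates are
the unique probability values; `t_F1` maximizes F1 with ties broken toward
the smaller threshold (favouring sensitivity); `t_S99` is the largest
candidate retaining ≥ 99% sensitivity, falling back to pass-all when none
does. On the calibration data the `t_S99` guarantee holds whenever any
candidate achieves it. Feature selection utilities follow common practice:
greedy correlation pruning at |r| ≥ 0.9 (alphabetically later feature of an
offending pair is dropped — any fixed rule works, this one is deterministic)
and minimum-redundancy-maximum-relevance forward selection in the
F-statistic / mean-|correlation| quotient variant. Whether a feature is
"normally distributed" (one published subset definition) has no canonical
test; subsets are arbitrary feature lists here, so any rule can be plugged
in.

Labeling semantics deserve one note: labels may be built against the LOW ∪
HIGH truth union (default, so true-but-discordant calls are not penalized)
or against HIGH only; both are exposed because the two conventions —
"agreement with low-confidence calls" for training versus "called in any
gold-standard set" for benchmarking — are not identical, and the package
does not pretend they are.

## Evaluation

TP = called ∩ truth, FP = called \ truth, FN = truth \ called, per pool or
per individual; confusion counts are summed before aggregate metrics are
computed (equal, by construction, to computing on the pooled event list).
Each pool is an independent comparison: a variant present in both of its
pools contributes one event per pool, deliberately and documented. Zero
denominators yield explicitly undefined metrics (`None`), never a fabricated
0; F1 is computed as 2TP/(2TP + FP + FN), which is 0 when TP = 0 but events
exist, keeping it usable for ranking. Rounding to 3 decimals (half away from
zero) happens only at serialization.

Bootstrap CIs resample call-level outcome events with replacement, n = 1000,
reporting the 2.5/97.5 percentiles. Because the metrics depend only on
category counts, replicates are drawn multinomially — exactly equivalent to
event resampling and much faster. Replicates with undefined metrics are
excluded and counted. The wrong-individual case is scored conservatively: a
variant assigned to the wrong carrier is an FP there *and* an FN at the true
carrier.

## Problem sizes used in checks

The shipped test-suite and acceptance-script configurations are desk-scale by
design: 10 × 10 matrices with 500 simulated sites (the acceptance grid uses
1200 sites over sizes 2–24 and coverages 5×/30×, two replicates), full
5 × 10 × 5 nested CV for the headline training run, reduced CV layouts in
smoke tests. These sizes make every number reproducible on one CPU in
minutes while leaving all algorithmic paths identical to larger runs.

## Known limitations

* Variant-level simulation: no read-level error profiles, PCR duplicates,
  strand artifacts, or reference bias; annotation distributions are synthetic
  and more separable than real caller annotations.
* Exact-key matching only; complex-region haplotype equivalence beyond
  left-alignment is out of scope.
* No pool-size/design optimization; the decoder resolves only private
  variants, and the private fraction shrinks as matrices grow.
* Genotypes and dosages within pools are not estimated.
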