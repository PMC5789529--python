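# Methods

## The problem

Quantitative transcriptional classifiers (SVMs, naive Bayes, nearest
centroid, …) consume raw expression magnitudes, which shift systematically
between laboratories, array batches and platforms.  Applying such a
classifier to a single clinical sample therefore requires normalizing that
sample together with a reference set measured under comparable conditions —
rarely possible in practice.  `reosig` implements the qualitative
alternative: classify a sample using only the *relative expression
orderings* (REOs) of gene pairs within that one sample.  Whether gene i's
measurement exceeds gene j's is unchanged by any strictly increasing
transform of the sample's values, so the decision needs no inter-sample
normalization at all.

## Signature model

For a gene pair (i, j) and a sample s, the orientation is `>` if
x_is > x_js, `<` if x_is < x_js.  Exact ties (possible in processed data)
and comparisons involving a masked measurement are tracked as separate
states; by default they support *neither* orientation, so they reduce a
pair's stability frequency rather than inflating it (a
`undefined_policy="drop"` mode removes them from the denominator instead).

* **Highly stable pair** — one orientation holds in at least a fraction
  *t* of a group's samples (default t = 0.90, inclusive comparison).  When
  several reference groups are given (e.g. normal and IBD), stability with
  the *same* orientation is required in each group separately.
* **Reversal pair** — stable in the reference class and, with the opposite
  orientation, in the alternative class.  Pairs stable with the same
  orientation in both classes carry no signal and are discarded.
* **Reversal coverage rate** — sqrt(f_ref · f_alt), the geometric mean of
  the reference-orientation frequency in reference samples and the
  reversed-orientation frequency in alternative samples.  This is the
  ranking statistic; equal rates break lexicographically by gene ids so
  output is deterministic across runs and platforms.
* **Cross-platform filter** — an optional second stage retests each
  candidate on an independent platform's cohorts (reference groups pooled)
  at the same kind of threshold; pairs whose genes are unmeasured there are
  dropped and logged.  Requiring consistency on two measurement principles
  is what makes the surviving pairs portable to third platforms.
* **k selection** — for every odd k up to `k_max` (default: all pairs),
  the training samples are classified with the top-k majority vote and the
  geometric mean of sensitivity and specificity recorded; the smallest k
  attaining the maximum is selected.  Selection reuses the deployment
  classifier's exact abstention/tie semantics, so training scores and
  field behaviour cannot diverge.

### Classification

Each of the top-k pairs votes for the alternative class when its
orientation in the sample is reversed relative to the reference
orientation, for the reference class when it matches, and abstains on
ties, masked values, or genes missing from the sample.  The majority of
cast votes decides; an equal split (only possible with abstentions, since
k is odd) is reported as `indeterminate` rather than forced — the
conservative choice for a diagnostic aid.  Evaluation reports sensitivity
TP/(TP+FN) and specificity TN/(TN+FP) over determinate calls, plus strict
variants that count indeterminates as errors, and flags a rate as
undefined (never silently zero) when its denominator is empty.

## Replicate-variation analysis

The motivation for abandoning magnitudes is quantified on technical
replicates: per-gene CV = SD / mean across replicates of one RNA sample,
after assay-specific exclusions — StaRT-PCR-style tables drop genes with a
zero or missing value in any replicate; TaqMan-style tables drop genes
absent by cycle threshold (CT > 35 in any replicate by default; a
mean-CT-across-replicates mode is provided because either reading of
"average CT" is defensible, and neither is asserted as canonical).  The SD
uses the sample (n−1) denominator by default — appropriate for 3–4
replicates — with `ddof=0` available so both conventions can be compared.
CV is computed on the linear measurement scale as provided, never after
log transform.  Summaries report the percentage of included genes with
CV ≥ 10% and ≥ 15% (inclusive), with the included-gene count alongside.

## Synthetic data generator

`generate_cohort` emulates the statistical structure the method assumes,
so every stage is testable without external downloads:

* per-gene baseline log2-expression ~ Normal(6.0, 1.5) — a typical
  processed-microarray dynamic range of roughly 2^2–2^10;
* i.i.d. Normal(0, 0.5) log2 measurement noise per cell, i.e. ±40%
  typical variation, consistent with the replicate CVs the variation
  module measures;
* planted reversal pairs (default 20 disjoint pairs among 500 genes)
  share a baseline and receive class-dependent offsets ±δ/2 of opposite
  sign in the two classes.  δ solves P(Normal(δ, 2σ²) > 0) = p, i.e.
  δ = √2·σ·Φ⁻¹(p), making the within-class orientation probability *p*
  (default 0.97) an exact design parameter rather than an empirical
  afterthought.  In the p = 1 limit the pair's genes share their noise so
  the ordering is deterministic;
* non-planted pairs order class-independently, providing the null
  background for false-positive measurement.

Batch structure comes in two flavours.  `apply_sample_monotone_batch`
passes each sample through an increasing map 2^(a·log2 x + b); this is the
harmless component — orderings are provably unchanged — and carries
optional `base_slope`/`base_shift` terms for the *systematic* lab-level
component shared by a whole batch (the demonstration below uses
base_slope 0.8, base_shift −3: a re-measurement with compressed dynamic
range and 8-fold lower overall intensity, the regime in which classifiers
trained on one platform are applied to another without normalization).
`apply_genewise_batch` multiplies each gene row by an independent factor
2^(scale·z); this is the harmful component, which flips orderings of
closely ranked pairs when differently perturbed batches are pooled.
`generate_replicates` draws per-gene replicates with mean-one lognormal
noise whose σ = √ln(1+CV²) makes the population CV exactly the assigned
profile value.

All randomness flows through one `numpy.random.Generator` seeded
explicitly; identical seeds give bit-identical matrices, labels and
ground truth.

### What the generator does not emulate

Real cohorts have correlated genes (co-expression modules), heavy-tailed
and heteroscedastic noise, probe-level artifacts, varying tumor purity and
platform-specific detection floors.  Passing tests on this generator
therefore demonstrates the *algorithmic* contracts — exact counting,
invariance, correct selection rules, calibrated recovery under the stated
noise model — not clinical performance on any real cohort, which requires
the multi-cohort array/RNA-seq validation workflow the pipeline config
exists for.

## Numerical and design choices

* All-pairs counting is blocked over gene indices (default block 256) with
  counts accumulated per block, so ~2×10⁸-pair scans over ~20k genes run
  in bounded memory; the correctness contract is exact count equality with
  the naive per-pair, per-sample double loop, enforced in the tests
  against an independent brute-force implementation.
* Pairs are stored canonically with gene_i < gene_j lexicographically;
  swapping a pair's stored order flips the orientation flag but can never
  change set membership.
* Threshold comparisons are inclusive (≥), matching "at least 90%"
  semantics; thresholds must lie in (0.5, 1.0] so a pair's stable
  orientation is unique.
* Expression files are TSV with genes in rows; a `transpose` reader flag
  handles samples-in-rows files — orientation is never autodetected, since
  autodetection silently corrupts near-square matrices.  Cells equal to
  "", "NA", "nan" or "NaN" (configurable) are masked; parsing uses exact
  `float()` conversion so write→read round trips are lossless.
* Probe-level matrices collapse to gene level by dropping probes mapping
  to zero or multiple genes and averaging multiple probes per gene
  (arithmetic mean per sample over unmasked probe values).
* The centroid baseline breaks distance ties to the first class in sorted
  class-name order, deterministically.  It is a deliberately plain
  stand-in for magnitude-based classifiers, used only to demonstrate
  fragility under batch transforms.

## Problem sizes used in the shipped checks

The test suite and `scripts/acceptance.py` run discovery at 500 genes ×
100–200 samples per class with 20 planted pairs, oracle comparisons on
matrices up to 200 genes × 50 samples, and the majority-vote closed-form
check on 2000 held-out samples — sizes at which every run completes in
seconds while the binomial error bars are tight enough for 3-standard-
error agreement tests.

## Known limitations

* Discovery requires both classes on the discovery platform; there is no
  unsupervised or one-class mode.
* The reversal-pair definition is strictly binary; rank-difference
  magnitudes and weighted variants are out of scope.
* Pooling cohorts assumes each sample's within-sample orderings are
  trustworthy; severely saturated or floor-censored measurements produce
  ties, which count against stability but are not modelled further.
* The fragility demonstration quantifies one specific (monotone) batch
  mechanism; gene-wise perturbations degrade REO methods too, as the
  generator's own erosion property shows.
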