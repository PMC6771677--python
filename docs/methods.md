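# Methods

This note documents the statistical procedures implemented in `mprameta`,
the design choices made where the design was genuinely open, what the
synthetic-data generators emulate, and the package's known limitations.

## Activity quantification

The generative model treats the plasmid (DNA) count of a barcode as
Gamma-distributed and the RNA count, given the plasmid copies, as Poisson
with mean `α · D`, so the marginal RNA likelihood is negative binomial.
`estimate_alpha` is a deliberately minimal two-stage estimator of this model:

1. **Stage 1 (DNA).** A method-of-moments Gamma fit of the region's DNA
   counts records the library's copy-number moments (shape `m²/v`, scale
   `v/m`). The latent plasmid count of each barcode is taken to be its
   observed DNA count: the model places no observation noise between plasmid
   copies and DNA reads, and any shrinkage toward the Gamma mean would bias
   the noiseless case (constant DNA, proportional RNA) away from the exact
   ratio.
2. **Stage 2 (RNA).** α maximizes the NB2 likelihood of the RNA counts with
   the plasmid count as multiplicative offset, `Var = μ + φμ²`. At φ = 0 this
   reduces to the Poisson MLE, `α̂ = ΣR/ΣD`. The dispersion φ defaults to a
   single moment estimate pooled across all regions
   (`Σ[(R−μ̂)² − μ̂] / Σμ̂²` with ratio-estimate means) because per-region
   estimates are unstable at ≤ 30 barcodes. Standard errors come from the
   observed information (numerical second difference of the log-likelihood).

Barcodes with zero DNA are excluded from stage 2 with a logged count; a
region with no usable barcode is reported with undefined α and a diagnostic,
never dropped. Full nested-GLM machinery with covariate design matrices
(barcode or batch effects) is out of scope; the optional log-normal barcode
effect in the generator exists to probe robustness, default off.

**Active calling.** `z = (α − median_ref)/(MAD_ref · 1.4826)` with the
reference set being the negative controls when available, otherwise all
regions. The 1.4826 factor makes the MAD consistent with a normal standard
deviation, which justifies using the standard-normal survival function for
the one-sided (upward) p-value; enhancer calling is one-sided by design and
repressed-element calling is not implemented. Benjamini–Hochberg runs over
all regions with finite α; `active ⇔ q < 0.05` by default. The alternative
labeling rule `log2 α > 1.5` is provided (`threshold_active`, boundary goes
to inactive) because both labelings are useful for the paired-region
analysis; they are reported separately, never mixed.

## Featurization

Coordinates are 0-based half-open throughout; overlap means ≥ 1 shared base.
Four feature categories: `experimental` (binary track overlaps + per-factor
means), `predicted` (counts from pluggable precomputed binding-score tables),
`kmer` (4^k binary presence features, k = 5 by default, plus composition and
motif-scan summaries), `locus` (promoter/exon/intron/distal, conservation,
closest-gene TPM).

Notable choices:

- **Motif significance** uses the exact score distribution of the log-odds
  under the background model, computed by dynamic programming over
  per-position scores discretized at 1e-3; the hit threshold is the smallest
  score with tail probability < 1e-4, minus the maximal accumulated rounding
  (granularity × motif length) so discretization never silently drops true
  hits. Both strands are scanned; reverse-strand hits are reported at their
  forward-strand start.
- **Motif density** is the maximum number of hit *start* positions in any
  20-bp window; overlapping hits of the same motif at different positions
  count separately.
- **"Above the 90th percentile" is strict** (`>`): with all-equal scores no
  region is counted, which keeps the tie behaviour deterministic.
- **Expression strata**: factors are sorted by TPM descending; `high` is the
  top `s` (default 100), `low` the bottom `s`, `med` the centred block of
  `s` factors (`⌈(m−s)/2⌉` offset).
- **Shuffled-mean control**: the TFBS cell-mean's negative control redraws
  the same number of non-cell-type TFBS tracks 100 times (seeded) and
  averages their mean-overlap feature.
- **Missing continuous annotation** (e.g., a conservation track not covering
  the interval) is flagged `NaN`, never imputed to 0; absent binary
  annotation is 0.
- Deep-learning binding predictors and DNA-shape tables are *pluggable
  providers* (per-region score tables / per-sequence callables), not
  re-implemented or retrained here.

## Feature assessment

Seven regression tests (Pearson/Spearman/Kendall overall and on the top
activity quartile; Spearman against activity quintile index, ties binned
downward) and two classification tests (AUROC; AUPRC by step-wise
precision–recall integration). Classification significance is a two-sample
Kolmogorov–Smirnov test of positive- versus negative-labelled scores — the
two-sample form was chosen because no reference distribution is otherwise
defined. Constant features yield statistic 0 with p = 1, flagged rather than
failing. q-values are BH within each test across features.

Ranks: per test, correlations rank by |statistic| descending (a strongly
negative feature is as predictive as a positive one), AUROC/AUPRC by value
descending, ties averaged. The within-dataset rank is the median of the
per-test ranks (all nine when labels exist, the seven regression tests
otherwise); the comprehensive rank is the median of within-dataset ranks
across datasets, skipping datasets where a feature is absent. Robustness is
assessed by recomputing every statistic on 100 seeded 80% subsamples without
replacement (mean ± sd).

Note one boundary fact: for strictly increasing data the quintile-index
Spearman cannot reach exactly 1 because binning introduces ties; tests assert
> 0.95 there and exact 1 for the unbinned correlations.

## Prediction models

Regions are split deterministically into 10 sections: ids sorted
lexicographically, assigned round-robin. Datasets sharing regions inherit
each other's section assignments, so a shared region is always in the same
fold. Regression ensembles are elastic net (features standardized with
training-fold statistics only; L1/L2 mixing ratio 0.5, overall penalty at
the library default), random forest, extra-trees, and gradient boosting,
1,000 estimators each by default; classification ensembles are random forest
+ extra-trees. The ensemble prediction is defined as the arithmetic member
mean (of predictions or of positive-class probabilities). The shuffle null
retrains the identical composition on permuted training targets, leaving
test targets untouched; in cross-validation each fold permutes with its own
derived seed, and null statistics are read from the 10-fold mean, where
chance alignment of a single permutation (sd ≈ 0.1 in Spearman at n = 2000)
averages down by √10.

Cross-dataset evaluation trains on nine sections of the source dataset and
tests on the held-out section of the target; training rows matching a
test-fold region by id, or overlapping one genomically when intervals are
supplied, are removed before fitting. With identical datasets this reduces
exactly to within-dataset cross-validation. Classification folds whose test
labels are single-class are skipped with a diagnostic, not failed, so small
simulated datasets still evaluate.

Tests and the acceptance script run the members with 30–200 estimators: the
ensemble contracts and recovery properties they check are insensitive to the
estimator count, and the smaller forests keep the default suite fast on a
single CPU. The 1,000-estimator default is what an analysis run should use.

## Transfer hardness

Shared regions are categorized by the 2×2 of their binary activity calls
(common-active / specific to either dataset / inactive in both); either the
FDR call or the log2-cutoff rule can supply the labels. Hardness of a region
under a classifier is `|label − predicted probability|` rank-normalized to
`(rank − 1)/(n − 1)` with average ranks for ties, making it invariant to any
strictly increasing transform of the raw differences. Predictions are only
defined fold-wise, so hardness is computed on the pooled held-out
predictions. Categories with fewer than 10 regions are excluded from the
ECDF/KS comparison with a diagnostic.

## Predictive TFs

A TF is predictive when its per-region binding score correlates with
activity (Spearman, two-sided p, BH across TFs, q < 0.05), high-confidence
at q < 0.01, nonpredictive at q > 0.1, indeterminate otherwise; the
correlation sign is kept. Overlap between two datasets' predictive sets is
tested with the upper-tail hypergeometric p (enrichment is the question) over
the universe of TFs scored in both datasets, fold enrichment
`overlap · N / (|A|·|B|)`, BH across dataset pairs. The expression
association is a two-sided Wilcoxon rank-sum of the TPM of the 50 best-
versus 50 worst-ranked TFs, reducing k symmetrically when TPM values are
missing.

## Variant effects

A variant is represented by the difference between variant and wild-type
sequence-intrinsic feature vectors (k-mer presence, #GC, polyA/T runs,
motif-scan summaries, pluggable per-sequence score providers): positional
annotations are identical between alleles and carry no signal. The difference
of an allele against itself is exactly zero and differencing is antisymmetric
by construction; concatenation of the two allele vectors is available behind
a flag. Discrete effects (−1/0/+1) use a 10-member ensemble (5 random
forests + 5 extra-trees classifiers), one model per element class, class by
mean probability with ties broken toward the lowest class. Continuous
effects default to one model per element — the stronger strategy when
effect scales differ between elements — with class-specific rosters:
promoters 1 RF + 1 ET + 1 GB, enhancers 5 RF + 5 ET; all tree members use
sqrt-of-features splits, and member seeds are base seed + member index.

## What the generators emulate — and what they do not

- `simulate_counts` reproduces the Gamma–Poisson count hierarchy exactly as
  the estimator assumes it, with a two-component log-normal transcription
  rate (inactive centred at log2 α = 0; active shifted by 2 by default, sd
  0.5, 30% active) and controls always inactive. Defaults (Gamma shape 4,
  scale 25, 30 barcodes) give realistic overdispersed libraries but are not
  calibrated to any particular published library, whose dispersion regimes
  vary. No sequencing error, PCR jackpotting, or barcode collisions.
- `simulate_paired_datasets` realizes activity as a shared linear component
  plus dataset-specific linear components plus noise over one region set —
  the minimal structure that makes cross-dataset transfer informative. Both
  datasets expose the full feature namespace, so degradation comes from the
  unlearnable specific component, not from missing features.
- `simulate_sequences` plants motif consensus sequences into i.i.d.
  background at a configurable GC fraction; truth records insert positions
  for scanner-recovery tests.
- `simulate_saturation` derives variant effects from disrupting planted
  binding sites: a site's substitution effect is the site strength times the
  change in motif log-odds at that offset, rescaled so nonzero effects have
  the configured spread; positions outside sites have exactly zero effect
  (the null mass, ~80% of positions by default). This is the mechanism that
  makes effects *learnable from sequence features* — repeated site
  occurrences share local context — and it mirrors how regulatory variants
  act; i.i.d. random per-position effects would be unpredictable for any
  sequence-based model at unseen positions. Discrete classes threshold the
  *noiseless* effect so recovery tests have unambiguous truth. Real
  saturation data additionally contains position-autocorrelated noise,
  indels, and promoter-specific effects that the generator does not emulate,
  so passing tests demonstrate correct mechanics and sensible statistical
  behaviour, not benchmark performance on real assays.

## Numerical choices and degenerate inputs

- NB likelihood optimization is bounded to `α̂_ratio × [1e-3, 1e3]` with
  absolute x-tolerance `1e-9 · α̂_ratio`; all-zero RNA gives α = 0 with a
  diagnostic.
- BH is delegated to a standard step-up implementation; empty p-vectors pass
  through.
- A zero MAD in the reference set, single-class labels, constant regression
  targets, duplicate region ids, and mismatched region-id sets are all
  rejected with messages naming the offending object; constant feature or
  score columns are flagged (statistic 0, p 1, or membership indeterminate)
  rather than rejected.
- All randomness flows from explicit integer seeds; every generator and
  model refit is bit-reproducible given its configuration.

## Problem sizes used in the test suite

The bundled tests and the acceptance script exercise the pipeline at 500–
2,000 regions, 10–30 barcodes per region, 100–200 TFs, and 300-bp elements
(900 variants) — sizes at which every statistical property checked (rate
recovery ρ ≥ 0.95, null calibration ≤ FDR, planted-feature rank 1, shuffle
nulls, transfer degradation, hardness dominance, variant recovery ≥ 0.5) is
stable across seeds while the whole suite stays fast on one CPU.

## Known limitations

- No differential (condition-comparative) MPRA testing; quantification only.
- The elastic-net penalty strength is the library default; "0.5" is read as
  the L1/L2 mixing ratio.
- Closest-gene assignment is consumed from a provided table, not computed.
- No genome-wide featurization or liftover; no indel support in the variant
  module.
- The KS "significance of classification" is a pragmatic two-sample choice;
  a one-sample variant against a reference distribution would be an equally
  defensible reading.
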