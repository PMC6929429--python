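# Methods

## Background and scope

A-to-I RNA editing converts adenosine to inosine in double-stranded RNA;
sequencers read inosine as guanosine, so an edited site shows G-containing
reads where the genome has an A. In adult diffuse glioma, the editing
profile separates the three WHO molecular subtypes — IDH wildtype, IDH
mutant with 1p/19q codeletion, and IDH mutant without codeletion — well
enough to predict IDH and codeletion status from RNA-Seq alone. glioedit
implements that analysis as a reusable pipeline operating on per-site read
counts: quantification, discriminative-site selection, cross-validated
classification, and downstream statistics. Read-level editing detection
(REDItools-style pileups, hyper-editing alignment) and site annotation
(ANNOVAR) are upstream of this package: counts and the site catalog are
inputs.

## Editing quantification

For site *i* and sample *j* with `g_ij` edited-G reads out of `n_ij`
covering A+G reads, the site-specific editing level is `e_ij = g_ij /
n_ij`, undefined (missing) when `n_ij = 0`. The total editing level of a
sample over a site set *S* pools counts before dividing: `E_j = Σ_{i∈S}
g_ij / Σ_{i∈S} n_ij`, i.e. the coverage-weighted mean of site levels, which
makes it invariant to splitting a site's reads across pseudo-sites.

Sites overlapping DNA variants are removed in two modes: *sample-specific*
masking blanks only the flagged (site, sample) cells (a somatic mutation or
private germline variant mimics editing only in that sample), while
*global* masking drops known-variant sites for every sample — the mode a
clinical deployment needs, since germline calls are not available per
patient. Total editing is computed after sample-specific masking; whether
masked cells should contribute is not externally specified, and excluding
them is the conservative choice (a DNA variant inflates the apparent edited
fraction).

Group comparisons of total editing use the two-sample Kolmogorov–Smirnov
test (asymptotic p), run pairwise between subtypes and optionally within
each tumor grade. The pairwise p-values are reported raw, without
multiplicity adjustment, matching how such screens are conventionally
presented.

## Site selection: Type I/II/III and MAD_3Q

Each (site, sample) cell is assigned exactly one type:

* **Type I**: `g_ij ≥ 3`, `n_ij ≥ 10`, and the editing frequency is
  significantly above a 0.1% background by a one-sided exact binomial test
  with BH-FDR < 0.05. The 0.1% background is the scale of Illumina
  base-call error; a cell failing it is indistinguishable from noise.
* **Type II**: `n_ij ≥ 10` but `g_ij < 3` or the test is not significant.
* **Type III**: `n_ij < 10` — too shallow to call either way.

The binomial p-value is `P(X ≥ g_ij)` for `X ~ Bin(n_ij, 0.001)`, computed
exactly. The BH family is, by default, all tested cells of the dataset
jointly (one FDR threshold for the whole screen); `per_site` and
`per_sample` families are available as a mode flag since the family choice
shifts individual Type I calls.

Sites are then filtered in two stages: (1) drop sites that are Type III in
strictly more than 25% of samples (chronically under-covered); (2) keep
sites that are Type I in at least 25% of samples (inclusive) **and** have
MAD_3Q > 0. MAD_3Q is the median of absolute deviations of a site's
editing levels from their third quartile. Anchoring the deviation at Q3
instead of the median retains sites edited in only a minority of samples:
for a site edited in, say, 30% of the cohort, the median level is 0 and an
ordinary MAD can vanish even though the site is informative, while Q3 sits
inside the edited minority.

Two conventions are configurable because they are not externally fixed:
Q3 uses linear interpolation between order statistics (position
`(n−1)·0.75`, the numpy/R-type-7 default), and MAD_3Q is computed on
non-missing levels from samples with ≥ 10 reads (Types I/II) — ratios from
under-covered cells are too noisy to contribute variability evidence.
A useful exact property of the statistic: MAD_3Q is zero iff a strict
majority (`⌊n/2⌋+1`) of the deviations from Q3 are zero.

## Classification

Two binary tasks: IDH mutation (positive = mutant) over the whole cohort,
and 1p/19q codeletion (positive = codeleted) restricted by default to
IDH-mutant samples, where the codel/non-codel question is clinically posed
(a full-cohort mode exists). A three-group one-vs-rest mode produces three
binary label vectors. The positive-class orientation of SEN/SPE follows the
clinical question; it is a documented choice, not externally specified.

Learners are scikit-learn with default hyperparameters: linear-kernel SVM,
random forest, and AdaBoost on depth-1 stumps. Evaluation is stratified
10-fold cross-validation — each sample is scored exactly once as a test
case — with pooled test-fold predictions giving ACC = (TP+TN)/N, SEN =
TP/(TP+FN), SPE = TN/(TN+FP), the ROC curve over all distinct score
thresholds, and the trapezoidal AUC (equal to the Mann–Whitney concordance
probability). Stratification is the default because plain random folds can
starve a training fold of a class; a plain mode exists. "The whole dataset
was completely assessed" is read as the 10 folds each serving once as the
test set, not a 10×10 repetition.

Feature selection, when enabled, is refit entirely inside each training
fold (the test fold never influences the chosen sites; a test instruments
this). Importance is the absolute linear weight for the SVM and
impurity-based importance for the ensembles. The retention rule is
importance ≥ mean importance for SVM and random forest, and nonzero
importance for AdaBoost (each stump consumes one feature, bounding the
selection at `n_estimators`); a top-*k* override exists. The exact rule
behind the originally reported per-fold counts is not recoverable, so the
rule here is the simplest scale-free default.

Sites selected in ≥ 5 of the 10 folds form the "repeatedly selected" set
used downstream; samples misclassified in *every* supplied run (across
learners/configurations) are flagged as continuously misclassified —
in practice a shortlist for label re-review.

Missing feature values are imputed as 0 (biologically "unedited"; selected
sites are well-covered by construction, so imputation is rare); mean
imputation is available.

Paired AUCs of two learners on the same samples are compared with the
DeLong test: placement values of each score vector give an unbiased
estimate of the covariance matrix of the two empirical AUCs, and the AUC
difference over its standard error is referred to a standard normal,
two-sided. Two identical score vectors (zero variance, zero difference)
return p = 1 by convention.

## Downstream statistics

* **Heatmap preparation**: per-site z-scores (population sd by default,
  configurable) and deterministic hierarchical leaf orders (scipy
  agglomerative clustering; average linkage, Euclidean distance by default
  — the original figure's choices are unstated, so these defaults are not
  claimed to match; ties resolve by observation index).
* **Locational enrichment**: for each genic category, the count of
  repeatedly selected sites in the category is referred to an exact
  hypergeometric law against the retained-site background; both tails are
  reported (`p_enrich = P(X ≥ k)`, `p_deplete = P(X ≤ k)`), raw, without
  correction across categories.
* **Survival**: samples are ranked by editing level at one site; the bottom
  25% (Q1) and top 25% (Q3) — group size `⌊n/4⌋`, ties broken by stable
  sample order — get Kaplan–Meier curves and a two-group log-rank test.
  Samples with missing time/event are dropped, and samples observed beyond
  a 10-year horizon are dropped entirely by default (mirroring the stated
  sample removals); a censor-at-horizon mode is provided. A group with zero
  events yields a statistic with a warning.

## Synthetic editome generator

The generator produces the statistical structure the pipeline assumes, plus
ground truth for recovery tests. It emulates a three-subtype glioma cohort;
its defaults are the desk-scale study conditions used throughout the tests:

| parameter | default | meaning |
|---|---|---|
| `n_sites` | 500 | catalog size |
| `n_samples_per_subtype` | (100, 100, 100) | wt / mut-codel / mut-non-codel |
| `category_proportions` | .40/.20/.15/.08/.07/.05/.03/.02 | UTR3, intergenic, intronic, downstream, ncRNA_intronic, exonic, upstream, UTR5 |
| `known_variant_fraction` | 0.05 | sites flagged as DNA variants |
| `coverage_mean`, `coverage_dispersion` | 50, 5 | negative-binomial total reads |
| `low_coverage_fraction` | 0.10 | cells forced to Uniform{0..9} totals |
| `baseline_editing_shape_a/b` | 1.5, 8 | Beta prior of per-site baseline level (mean ≈ 0.16) |
| `n_discriminative_idh/codel` | 40, 40 | planted sites per task |
| `effect_size_idh/codel` | 0.2 | additive level shift, clipped to [0,1] |
| `within_site_overdispersion` | 0.02 | 1/concentration of the beta-binomial |
| `prognostic_site_hazard_ratio` | 3 | hazard multiplier per unit editing level |
| `baseline_hazard` | 0.17 /yr | hazard at editing level 0 (median ≈ 4 y) |
| `censor_low/high` | 2, 12 y | independent uniform censoring window |

Design choices: coverage is negative-binomial because RNA-Seq depth is
overdispersed, with a forced low-coverage fraction so the Type III filter is
exercised at a controlled rate; edited counts are beta-binomial (each cell's
rate beta-distributed around its site's subtype mean with concentration
`1/within_site_overdispersion`), reproducing the between-sample variability
MAD_3Q measures; effects are additive mean shifts with a random sign that is
downward in the affected group 80% of the time, so IDH-mutant samples have
lower total editing, as the real subtypes do. Grade composition per subtype
follows the real cohort's table (grade IV concentrated in IDH-wildtype,
absent from codeleted tumors), with unknown-grade rows dropped and
renormalized. Category proportions respect the published ordering
(UTR3-dominated); the real bar chart prints no numbers, so they are free
knobs, not a TCGA match.

Survival is proportional-hazards: sample hazard `λ_j = λ_0 · HR^{e_j}`
with `e_j` the level at the planted prognostic site, exponential event
times, independent uniform censoring, OS and PFI drawn independently (PFI
at 1.4× baseline hazard). The prognostic site is given a broad bimodal
level distribution (Beta(0.45, 0.45), identical across subtypes), so its
quartile groups differ by nearly a unit of editing level and the planted
per-unit hazard ratio expresses almost fully between Q1 and Q3 — the
synthetic analog of a clearly separated prognostic 3'UTR site. All
randomness flows from a single integer seed; identical seeds give
bit-identical outputs.

What the generator does **not** emulate: linkage disequilibrium between
sites (sites are independent given subtype), ADAR-expression-driven
correlation of editing across sites within a sample, batch effects,
non-proportional hazards, or dependent censoring. Passing recovery tests
therefore shows the pipeline recovers planted structure under its own
model assumptions, not that real TCGA performance is reproduced — the
original cohort's headline numbers require the real BAMs.

## Numerical choices and problem sizes

Exact tails come from scipy (`binom.sf`, `hypergeom.sf/cdf`); BH from
statsmodels; ROC/AUC from scikit-learn; KM/log-rank from lifelines. The
DeLong covariance uses midrank placements with `ddof=1`. Degenerate inputs:
zero-coverage cells become missing rather than erroring; an empty selection
result is a warning (downstream stages then fail with a clear "no features"
error); a zero-variance site is an error naming the site in z-scoring and
is filtered (MAD_3Q = 0) in selection.

Test and acceptance problem sizes are chosen for a laptop-class single
core: the recovery suite uses the default 300-sample × 500-site cohort;
survival calibration uses 200 replicates at n=100 (power) and 500
replicates (null uniformity); DeLong calibration 500 replicates at n=60;
FDR calibration 200 screens of 2000 cells. The full pytest suite runs in
about four minutes; `scripts/acceptance.py` in well under one.

## Known limitations

* The pipeline consumes pre-computed counts; alignment artifacts,
  hyper-editing, and strand orientation must be resolved upstream.
* Per-fold feature-selection thresholds are a package choice; the original
  analysis's thresholds are unrecoverable from its text.
* The hypergeometric background is whatever site set is supplied; with the
  synthetic generator it is the retained set, which is itself
  selection-biased — as in the original design.
* Three-class mode is one-vs-rest only; no multiclass calibration.
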