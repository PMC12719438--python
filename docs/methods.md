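# Methods

## Synthetic multi-cohort generator

Each sample's composition starts from a global base log-abundance vector
over `n_taxa` species (default 120) dominated by four *Lactobacillus*
species (base logits 5.5/4.0/3.5/3.0 against N(0,1) for the rest), the
field-typical structure of vaginal communities. Per cohort, a log-normal
batch effect N(0, `batch_effect_sd`²) per taxon is added (default sd 1.0);
per sample, standardized age, BMI and ethnicity enter linearly on the logit
scale through fixed sparse loading vectors scaled by
`covariate_effect_sizes` (defaults 0.3/0.2/0.3), with the leading
*Lactobacillus* loading forced negative so that older/higher-BMI samples are
less *Lactobacillus*-dominated. EC samples get (i) their logits tempered by
1/(1 + `diversity_shift`) (default 0.3), flattening the expected composition
and hence raising expected Shannon entropy, and (ii) `+ec_log_fold_change`
(default 1.5, natural log) added to five designated *Peptoniphilus*-like
species. Proportions are drawn from a Dirichlet with concentration 50 around
the softmax of the logits (Dirichlet-multinomial overdispersion, typical of
16S counts); counts are multinomial at Poisson depths around
`sequencing_depth_mean` (default 10,000; published cohorts do not report
depths, so this is exposed in the config — the analysis scripts and tests
use 5,000/2,000 for speed).

Cohort sizes, EC counts and the per-class age/BMI means mirror the
five-cohort design the pipeline targets (two cohorts lack printed
age/BMI values; field-typical values are substituted). Vaginal pH is
generated as 7.0 − 3.5 × (*Lactobacillus* fraction) + N(0, 0.3) and
dichotomized at 4.5; with the default dominance this yields roughly 30% of
benign and few EC samples at pH ≤ 4.5. Covariate availability follows a
per-cohort plan (three full cohorts, one age-only, one with no metadata);
where pH is available it is additionally missing at random with
label-dependent rates (8% benign, 20% EC), mirroring the label-dependent NA
rates real cohorts report. The global seed expands through
`numpy.random.SeedSequence.spawn` into one stream for shared structure
(taxonomy order, base logits, loadings, tree) plus one per cohort, so adding
a cohort never perturbs earlier ones.

What the generator does **not** emulate: read-level artifacts (chimeras,
primer bias, taxonomy-assignment error), phylogenetic correlation of batch
or covariate effects, zero-inflation beyond what the
Dirichlet-multinomial produces, and longitudinal structure. Passing tests
therefore demonstrate correctness of the statistical machinery under a
plausible compositional model, not performance on real sequencing data.

## Feature engineering

Fixed order: genus aggregation → prevalence filter → CLR. Species
unassigned at genus are pooled under their deepest resolved ancestor
(suffix `_unclassified`). "Present in fewer than 5% of samples" is read
strictly: a taxon at exactly the threshold is kept. The CLR uses
clr(x)ᵢ = ln(xᵢ + c) − meanⱼ ln(xⱼ + c) with pseudocount c = 0.5 (the
half-count convention; configurable) — depth invariance holds only in the
large-count limit and is tested there. The surviving-taxon list is always
learned on training data and frozen before being applied to evaluation data
(absent taxa re-enter as zeros); for late integration each cohort learns its
own filter, for early integration the pooled training set does.

## Ecology

Distances follow the textbook definitions; Jensen-Shannon uses natural
logs and is returned as the square root (a metric) by default, with a
switch for the raw divergence. UniFrac walks every non-root edge of the
supplied tree: unweighted = unshared/union branch length over
presence-absence; weighted = Σ bₑ|Aₑ−Bₑ| / Σ bₑ(Aₑ+Bₑ) with Aₑ the
proportion of sample A descending edge e (on a star tree with equal branch
lengths this reduces to half the Manhattan distance, a closed-form check in
the tests). PERMANOVA Gower-centers the squared distance matrix and tests
each design column **marginally**: SS(term) = SS(full) − SS(full without
term), pseudo-F against the full-model residual, p by free permutation of
observations with p = (1 + #{F* ≥ F}) / (1 + n_perm), ties counting toward
the numerator; an exhaustive-enumeration mode exists for tiny n. Rows with
missing values in any tested term are dropped and reported. No
multiple-testing correction is applied across terms.

## Differential abundance

Log counts (pseudocount 0.5) are modelled per taxon as a linear function of
disease plus adjustment covariates, with a per-sample offset absorbing the
unknown log sampling fraction. The offset iteration (median residual per
sample) is only identified up to the design column space — any offset
pattern the design can express is re-absorbed by the per-taxon OLS refit —
so the update is projected onto the design-orthogonal complement
(convergence in a few iterations), and the design-space component of the
bias is then absorbed once: for each non-intercept coefficient the median
of its estimates across taxa (zero under a null majority) is subtracted
from every taxon and moved into the offsets. Inference is a Wald test with
the exact small-sample t reference (residual dof) rather than the
asymptotic normal, and Holm step-down across taxa. Null calibration
(family-wise error at the generator's null) and recovery of planted
enrichment are part of the acceptance suite. Note that under the
generator's diversity shift *most* taxa truly change with disease, so the
null-majority centering defines effects relative to the typical taxon —
the planted enrichment still dominates the ranking.

## Batch correction

Parametric empirical-Bayes location/scale adjustment of CLR features:
standardize against a design containing batch indicators plus the protected
covariates (the disease label by default — correcting without protection is
possible via `protect=None` and is the documented overcorrection risk),
estimate per-batch per-feature means and variances on the standardized
scale, shrink them toward normal / inverse-gamma priors with
method-of-moments hyperparameters, remove, and restore the grand mean and
protected effects. Zero-variance features are floored (1e-8) and recorded.
A fitted `BatchModel` can be applied to a cohort unseen in training: the
new batch's own location/scale estimates are shrunk with self-contained
moment priors against the frozen grand mean and pooled variance — no
training parameter is refit and no label is used, which is the leakage
policy for the early-integration held-out path.

## Rebalancing and imputation

SMOTE-NC raises the minority class to `target_ratio` × majority (default
1.0): synthetic samples interpolate numeric features (uniform λ) between a
minority seed and one of its k = 5 nearest minority neighbors (clipped to
minority − 1), take categorical values by neighbor majority vote, and the
neighbor metric adds the squared median numeric standard deviation once per
differing category. Chained-equation imputation cycles incomplete covariate
columns (5 iterations) through per-column models — leave-one-out-CV ridge
for numeric targets, logistic regression for categorical — conditioned on
the other covariates and the microbiome block, all predictors z-scaled with
frozen training moments; observed cells are never altered, models are
frozen for evaluation-time use, and a wholly missing covariate raises an
error instructing per-cohort exclusion rather than cross-cohort imputation.
Single completions (not multiple imputation) are used, as prediction
pipelines require; the order is impute → rebalance, inside training folds
only.

## Ensemble framework

Base learners — random forest, gradient-boosted trees, single-hidden-layer
network — sit behind a uniform fit/predict-probability interface (backed by
scikit-learn and xgboost); the framework owns everything else. Per training
unit (one cohort for late integration, the pooled training set for early),
each grid point is scored by 5-fold stratified CV repeated 3 times (folds
reduce automatically when a class is smaller than the fold count, logged),
with imputation and SMOTE-NC re-fit inside each training fold, and the mean
out-of-fold F1 at threshold 0.5 decides; ties prefer the simpler
configuration, then grid order. By default the three tuned families are
probability-averaged within a unit (`combine="best_family"` switches to the
single best); across units the ensemble takes the unweighted arithmetic
mean of local probabilities (a flag weights by out-of-fold F1), and a mean
of exactly 0.5 classifies positive so the rule is total. Variants: pooled
raw, pooled batch-corrected, and late ensembles on taxa only, covariates
only (cohorts with no usable covariate are skipped and logged), covariates +
pH, covariates + taxa (covariate-free cohorts contribute taxa-only local
models). A local model may only use covariates observable in the held-out
cohort; LOSO validation re-restricts and retrains per round and reports
per-study metrics plus micro-pooled confusion counts and pooled AUROC over
the concatenated out-of-study scores.

## Evaluation

Proportion metrics carry exact Clopper-Pearson intervals
(lower = Beta quantile α/2 with (x, n−x+1); upper = 1−α/2 with (x+1, n−x);
closed forms at the boundaries); zero-denominator metrics are flagged
undefined with CI [0, 1] and serialize as null. AUROC is the rank/
Mann-Whitney statistic with ties counted ½ and is undefined for single-class
sets. No AUROC confidence intervals are produced by default (a bootstrap
exists behind a flag); published AUROC CI conventions vary and are not
reproduced.

## Problem sizes and numerical choices

The test and acceptance runs use sequencing depth 5,000 (2,000 for the
smallest fixtures), one-point random-forest grids with one CV repeat, 3–20
simulation seeds per property, 99–999 permutations, and 200 replicates for
null calibrations — sizes chosen so the whole suite runs in minutes on one
CPU while leaving the Monte-Carlo bands meaningful. Convergence tolerances:
offset iteration 1e-6 (max 100 iterations, non-convergence reported with
the step trace), EB shrinkage 1e-6, CLR zero-sum asserted at 1e-9.

## Known limitations

The differential-abundance procedure is a deliberately self-contained
bias-corrected log-linear model, not a reimplementation of any published
tool's exact estimator (no structural-zero classification, no EM sampling-
fraction step). The batch model assumes roughly Gaussian CLR features.
The generator's covariate-composition coupling is linear on the logit
scale. PERMANOVA uses free permutation only (no residual permutation or
strata). Real-data performance claims are outside what this repository can
establish; all quantitative results here are on synthetic data whose ground
truth the generator controls.
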