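# Methods

This note records the modelling assumptions, parameter choices, and known
limitations behind `tempheno`, in the order data flows through the package.

## Time representation

All timestamps are non-negative `days_before_anchor`; the anchor is AMI
onset for cases and the last encounter for controls. The five-year window
(1,830 days) is cut into ten 183-day bins, numbered 0 (oldest) to 9 (most
recent). Bins are half-open `(older, newer]`: an event exactly 183 days
before the anchor belongs to bin 8, and day 1,830 is clipped into bin 0.
Working anchor-relative avoids calendar arithmetic entirely, at the cost of
not modelling seasonality.

## Synthetic cohort generator

The generator emulates the statistical shape of a matched outpatient
extract, not its clinical content. Ground truth is a set of R planted
rank-one phenotypes: patient loadings `A ~ Uniform(0,1)`, peaked Gaussian
temporal signatures over the ten bins (centres spread over bins 2–8, width
1.5 bins), and sparse non-negative feature profiles (each phenotype loads
~35% of the features in every domain). Defaults and what they represent:

- `encounter_rate = 4 /year`, truncated-Poisson encounter counts with a
  minimum of three visits (the cohort inclusion rule), encounter days
  uniform over the window. An optional `ensure_bin_coverage` flag adds one
  encounter per bin; it exists because a bin without encounters zero-fills
  and breaks exact low-rankness, which the noiseless recovery checks need.
- Labs: `value = baseline_f + 25 · Σ_r A_ir B_br C_fr + N(0, noise_sd)`,
  baselines uniform on [60, 140], `noise_sd = 1`, each measurement missing
  with probability 0.3 at each encounter.
- Diagnoses/medications: per six-month bin, presence is Bernoulli with
  `logit = −2.5 + 4 · Σ_r A_ir B_br C_fr`, sampled only in bins with an
  encounter. The logit link keeps the binary tensors approximately low-rank
  so recovery against the planted factors is well defined.
- Outcome: `label ~ Bernoulli(sigmoid(b + coefs · A_i))` with the intercept
  solved (Brent) so expected prevalence is `1/(1+control_ratio)`; the
  default effect is +1.5 log-odds on the first phenotype's membership. The
  driving phenotype peaks mid-history, which is exactly the regime where a
  latest-value snapshot is blind and temporal phenotyping should help.
- Demographics: age ~ N(64, 13) clipped to 23–89, 57% male, race
  categorical; family history is an independent Bernoulli(0.45) over the
  qualifying cardiovascular condition list.
- Frailty: the hospital-frailty-style score is the sum of weights of
  distinct diagnosis codes under the shipped weight table. The table
  (`data/frailty_weights_synthetic.tsv`) is a synthetic stand-in with the
  right shape — ICD-10-like categories mapped to points — not the published
  catalogue, which stays pluggable.

Matching is greedy without replacement: cases in ascending patient id, exact
on sex, |Δage| ≤ 2 years, |Δfrailty| ≤ 2 points, nearest controls first
(|Δage|, then |Δfrailty|, then patient id). Greedy is not optimal matching;
it was chosen because it is deterministic and auditable, and the tie-break
order is a package convention. Cases that cannot obtain the full control
ratio are excluded. The 70/30 train/test split is done *by matched set*, so
a case and its controls never straddle the split.

What the generator does **not** emulate: disease progression, code
co-occurrence structure beyond low rank, measurement units/outliers,
informative missingness, calendar effects. Passing tests therefore show the
pipeline recovers planted structure under realistic sampling noise — not
that it would perform at any particular level on real records.

## Preprocessing

Fixed order: value cleaning → ICD9→ICD10 mapping → Z-chapter removal →
3-character roll-up → train-fitted filters. Cleaning drops non-parsable
numerics and values outside per-variable plausible ranges (shipped defaults
in `data/cleaning_defaults.yaml`; the range table is configuration, not
fact). Temperatures under 50 are taken as Celsius and converted to
Fahrenheit. The roll-up adds the 3-character category only (E11.0 → E11);
deeper intermediate levels are not generated. Unmapped ICD9 codes are
dropped rather than passed through, because a mixed vocabulary would corrupt
the roll-up.

Both filters use strict inequalities: continuous variables are kept when
*more than* 60% of training patients have a measurement; binary variables
are dropped when present in *less than* 1% of training cases **and** of
training controls. Filters are fit on the training split once and applied
frozen to both splits.

## Feature representations

- Latest values: per variable, the measurement with the smallest
  days-before-anchor; values older than `recency_window` (default 183 days)
  are treated as missing. The window is exposed because "most recent" and
  "within six months" are both defensible readings; 183 days is the default.
- Summary statistics: five-year mean, SD, min, max per continuous variable
  (sample SD, n−1; the SD of a single observation is defined as 0 rather
  than missing, to avoid re-imputing a quantity that exists), and an
  ever-present flag per binary variable.
- Lab/vital tensor: last value per variable per bin, discretised to levels
  1–5 by quintile edges fit on training values only. Duplicate edges
  collapse, so a variable with few distinct values gets fewer levels — the
  degeneracy is reported rather than hidden. Missing-in-bin is encoded 0,
  deliberately distinct from level 1: under non-negative factorisation,
  absence reads as low intensity.
- Dx/Rx tensor: diagnoses are 1 where documented, 0 at encounters without
  the code, null in encounter-free bins, then carry-forward + zero
  imputation (a bin is "with encounter" when any clinical event falls in
  it). Medications flag every bin their prescription interval overlaps
  (rows may carry an end day), with zero-fill and no carry-forward.

## Non-negative CP via HALS

Factors are updated column-wise with exact coordinate updates projected onto
`max(·, 1e−12)`; the floor avoids exactly-dead columns, and a column whose
norm still collapses below 1e−10 is re-seeded randomly (logged). The
objective (relative Frobenius error, computed per sweep by the Gram-matrix
identity) is non-increasing; iteration stops at relative improvement below
`tol` (1e−8) or `max_iter` sweeps. After fitting, B and C columns are
normalised to unit ℓ2 and the scale absorbed into the component weights, so
patient memberships are `A·diag(λ)`. Initialisation is seeded uniform
non-negative.

Held-out projection solves one NNLS problem per patient against the frozen
Khatri-Rao basis of (B, C). Rank selection fits replicate decompositions per
rank (default 3), trains a reference random forest on memberships with a 30%
patient holdout, and reports the metric-vs-rank table plus a
maximum-curvature elbow *suggestion* — the final rank stays a configuration
choice, because elbow reading is judgement, not optimisation. Recovery
diagnostics use factor congruence: the product over modes of cosine
similarities of greedily matched columns.

"Normalised patient membership" in phenotype reports divides each
membership column by its maximum (range [0, 1]); ℓ2 normalisation would be
the main alternative and differs only by a per-component constant.

## mRMR and imputation

Relevance is random-forest impurity importance computed once from a seeded
200-tree forest; redundancy is the mean |Pearson r| to the already-selected
set; the greedy score is their quotient. The redundancy denominator is
floored at `max(1e−6, 1/√n)` — the null scale of a sample correlation —
because with a near-zero floor a noise feature whose sample correlation to
the selected set happens to be ~0.001 wins the quotient over genuinely
informative features. Columns are put in lexicographic order first, making
the selection invariant to input layout, and ties break on feature name.
Relevance is computed once (not per step); per-step recomputation is the
alternative reading and would be a one-line change.

Post-selection kNN imputation (k = 5, a convention; Euclidean over mutually
observed features) is fit on training rows only and never updated from the
data it is applied to. Observed entries pass through bit-identically.

## TGFNN

Continuous features are min-max scaled to the training range (mild clipping
outside). Concept memberships are Gaussians with learnable centre and width,
initialised at the scaled 25th/50th/75th percentiles with widths of half the
inter-quartile gap (floored at 0.05); binary features contribute the two
concepts (absent, present). Training may "squish" a concept out of the data
range — allowed, and visible in extracted rules.

Concept attention is a masked softmax per (rule, variable); variable and
rule importances are softplus-reparameterised. The T-norm bridge is a convex
combination in the log domain, `L = τ·Σ g + (1−τ)·min g` with
`g = w·log s`: τ = 1 is the exact weighted product, τ = 0 the exact weighted
minimum, and a variable with importance 0 contributes neutrally. The
T-conorm mirrors this between sum and max in the linear domain. Both τ
parameters are trainable through a sigmoid. These bridges are package
conventions satisfying the stated endpoint behaviour; only the endpoints
are canonical.

Training is full-batch Adam (lr 0.05) on class-weighted cross-entropy with
hand-derived analytic gradients (verified against finite differences in the
test suite), L2 on raw weights (1e−4) plus an L1 penalty (0.01) on the
effective variable importances — the lasso pressure is what makes extracted
rules name only the variables that matter. Early stopping tracks F1 on a
10% holdout (patience 60 epochs by default) and keeps the best checkpoint.

Rule extraction ranks rules by their share of total positive-class
importance, prunes rules and per-rule variables below 0.1 relative
importance, and renders each survivor with its highest-attention concept
("glucose is high AND age is medium"). Rule-recovery studies train a small
number of replicates (default 3) and pool extracted rules across them, the
same way rules are read off cross-validation replicates; a planted rule
counts as recovered when its defining variables all appear in the top-3
weighted variables of some extracted rule.

## Evaluation machinery

Class weights are `N/(2·N_c)`; models that cannot take weights train on a
seeded 1:1 downsample of the majority class. Hyperparameter search draws
random grid combinations scored by mean F1 over 3 stratified folds (ties
keep the first draw); evaluation runs 5 stratified folds, each fold's model
scored on its validation fold and on the fixed test set (no refit on full
train — the fold models *are* the reported ensemble). Folds are stratified
throughout: the class imbalance makes unstratified folds fragile.

AUROC/AUPRC/F1 come from scikit-learn and are pinned to brute-force
pair-counting and step-integral oracles in the tests. Platt scaling fits
`p = 1/(1+exp(A·s+B))` by BFGS maximum likelihood (degenerate constant
scores fall back to an intercept-only fit, with a warning). Reliability
curves use ten equal-width bins with empty bins omitted. The calibration
check fits on a 2,000-sample logistic simulation and assesses the curve on
5,000 draws — at ~200 samples/bin the empirical gap of even a perfect
calibrator exceeds 0.05 in roughly a third of draws, so the binomial-bound
sample size is used for assessment.

Friedman's test (scipy, tie-corrected; pinned to a rank-arithmetic oracle)
gates all-pairs Nemenyi post hocs computed from the studentized-range
distribution, default alpha 0.01. The blocks×treatments orientation is the
caller's choice — both "folds as blocks" and "feature sets as blocks" are
legitimate designs. Kendall comparisons use tau-b. Permutation importance
(mean AUROC drop over seeded column shuffles) is the model-agnostic
attribution; dedicated attribution libraries can be layered on top through
the classifier contract.

## Problem sizes

The shipped studies run at desk scale, chosen so the full suite and the
acceptance script each complete in minutes on one CPU: planted-rank-4
tensors of 300×10×40 at SNR 10 for recovery; 2,000-patient cohorts (667
matched sets) over 10 paired seeds for the discrimination study; 1,500
training samples for the fuzzy-rule recovery study. Scaling the cohort or
rank up is a matter of configuration, not code.

## Known limitations

- The generator's independence assumptions (features, encounters, family
  history) are stronger than real EHR data; absolute metric levels on
  synthetic cohorts say nothing about clinical performance.
- Greedy matching and greedy mRMR are order-dependent heuristics; both are
  deterministic but neither is optimal.
- The TGFNN loss is non-convex; different seeds find different rule
  decompositions of the same decision boundary, which is why recovery is
  assessed across replicates.
- EBM and TabNet bindings are absent unless their libraries are installed;
  the registry degrades to the documented subset (dt, lr, rf, xgb, tgfnn).
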