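# Methods

## The problem

Clinical datasets routinely lose values for variables that are hard to
measure or record — here, the volume of a supratentorial intracerebral
hemorrhage, dichotomised at 30 ml, in a cohort of 1468 stroke admissions
(1207 discharged successfully, 261 discharge failures).  The question this
package operationalises is *decision-impact*: not whether an imputation
method restores the true value distribution, but whether the downstream
clinical decision model — a logistic regression predicting discharge
failure — behaves the same on the completed data as it would have on the
complete data.  The pipeline is therefore: generate a complete cohort,
ampute the volume variable under a controlled mechanism, impute it with
each of eight methods, refit the discharge model on each completed dataset,
and compare sensitivity, AUC and Cohen's kappa against the complete-data
reference fit.

## Synthetic cohort generator

The real cohort is not publicly available; only its per-outcome-group
categorical marginals are published.  The generator therefore supports two
modes.

**Exact mode** (default) assigns category values within each outcome group
by seeded permutation so that every per-group count is reproduced exactly.
Variables are conditionally independent given the outcome — the strongest
assumption the known marginals can support, and the mode used wherever a
test needs count-level fidelity.

**Stochastic mode** samples each record's categories from the per-group
proportions, optionally tilted by pairwise log-odds couplings.  Coupling
`λ` between variables *u* and *v* adds `λ·s(u)·s(v)` to the category
logits, where `s` is the category index normalised to [0, 1] (for binary
variables, the indicator of the second-listed category).  Sampling is
autoregressive in the declared variable order, so the tilted model is a
well-defined joint distribution and generation is deterministic given the
seed.  The default coupling map ties larger hemorrhage volume to deep coma
(λ = 2.5), operation (1.5) and co-infection (1.0) — clinically plausible
directions chosen once, at moderate strength, so that model-based imputers
have a within-group signal to learn.  Without any coupling all imputers
collapse to the marginal mode, which is exactly what conditional
independence implies.

What the generator does *not* emulate: the real joint dependence structure
(unknown), continuous hemorrhage volumes (the analysis dichotomises at
30 ml), and the source database's native missingness.  Consequently,
passing tests demonstrate that the pipeline's machinery is correct and
that its qualitative behaviour (model-based imputers beating mode fill
when predictors carry signal) is reproduced — not that the published
per-cell benchmark numbers are recovered, which would require the
undisclosed real joint distribution.

## Amputation

Missingness is univariate and monotone: only the volume column is masked.
The overall missing count is `round(p·n)` (half-up rounding for platform
stability) and is preserved exactly in every mechanism.

* **MCAR** draws that many cells uniformly over all records.
* **MAR 1:2 / 2:1** solve `m_f/n_f = r · m_s/n_s` for the per-group
  counts with `r` the failure:success missing-proportion ratio, round the
  success-group share, give the failure group the remainder, then draw
  uniformly within each group.  The ratio error is bounded by one cell;
  infeasible combinations (a group's allocation exceeding its size) raise.

The canonical grid is 3 mechanisms × proportions
{5, 10, 15, 20, 30, 50}% = 18 scenarios, each with a seed derived stably
(SHA-256) from a base seed, the mechanism and the proportion.

## Imputation methods

All model-based methods use the complete cases as the training set, with
the volume variable as the label and the seven other clinical variables
*plus the discharge outcome* as features (eight unexpanded predictors —
including the analysis outcome in the imputation model is standard
practice and matches the tuning grids).  Encodings follow each family's
convention: one-hot with unit-variance scaling for KNN/LR/NN/SVM and the
chained-equations regressions; ordinal integer codes (age 0–4) for the
random forest.

* **Mode** — modal observed category; ties break to the first-listed
  category ("<30 ml").
* **KNN** — Euclidean distances on the encoded non-target variables to
  every complete record; the k = 10 nearest donors' 0/1 codes are reduced
  by median; an exact 0.5 median falls back to the overall observed mode;
  distance ties break by record index.  All choices are deterministic.
* **Chained-equations PMM** — m = 20 independent chains of 50 iterations.
  Each iteration draws coefficients from the approximate posterior of a
  ridge-stabilised (ε = 10⁻⁶) least-squares fit of the 0/1 target code on
  the encoded predictors (σ² from the scaled inverse-χ², then
  β ~ N(β̂, σ²(XᵀX)⁻¹)), matches each masked record to its 5 nearest
  observed predictive means, and copies one random donor's value.  The
  final value is the chain average thresholded at 0.5, ties going to
  "≥30 ml".  With a single incomplete variable the iterations are
  statistically redundant (each redraws from the same complete-case fit)
  but are retained for procedural fidelity; the reduced profile shortens
  them.
* **LR / RF / NN / SVM** — scikit-learn estimators behind a common tuning
  surface: unpenalised logistic regression (ridge fallback with a warning
  on non-convergence), random forest with 500 trees and per-split feature
  subsampling `mtry ∈ {1..8}`, a single-hidden-layer perceptron
  (`size ∈ {1..24}`, weight decay ∈ {0, 0.1, 0.01, 5·10⁻⁴}, L-BFGS), and
  an RBF-SVM with cost `C ∈ {0.25, 0.5, 1, 2, 4, 8, 16, 32}` and
  bandwidth set by the median-pairwise-distance heuristic on the training
  features.  Grid search scores mean AUC over stratified 10-fold CV on the
  complete cases; the grid is enumerated in simplicity order (smaller
  size/mtry/C, larger decay first) and the first maximum wins, making tie
  breaks deterministic and parsimonious.  A minority class smaller than
  the fold count raises rather than silently degrading.
* **Stacking ensemble (EL)** — the four learners above are tuned as usual,
  then emit out-of-fold class-1 probabilities over the complete cases
  through a shared stratified split (out-of-fold rather than
  resubstitution, to keep the meta-learner from rewarding overfit
  stage-one models).  A second-stage RBF-SVM, cost tuned on the same grid
  against the 4-column meta-matrix, classifies the masked records from
  the stage-one models refit on all complete cases.

## Evaluation

The discharge model is a maximum-likelihood binary logit (Newton,
tolerance 10⁻⁸, 100 iterations) of the failure indicator on the one-hot
design with first-listed categories as reference levels; constant columns
are dropped, and separation triggers a lightly ridge-penalised fallback
with a warning.  Evaluation is apparent (resubstitution) by default,
mirroring the single reference fit on the complete data; a Youden-optimal
threshold mode is available, but the default cutoff is 0.5 — the
least-assumption choice, worth flagging because at 17.8 % prevalence it
yields lower sensitivities than a prevalence-adapted cutoff would.
Kappa is reported unclipped and can be negative.  AUC uses the rank
(Mann–Whitney) formulation with midrank ties.  Per-mechanism "Average"
rows are unweighted means over the proportion grid, rendered at three
decimals.

## Statistical comparison

For each metric × mechanism, the ensemble's six per-proportion scores are
paired with each of the seven competitors'.  The one-sided exact Wilcoxon
signed-rank test drops zero differences, midranks ties, and enumerates all
2ⁿ sign assignments of the (possibly tied) ranks — exact even under ties,
which is why a clean n = 6 sweep gives p = 1/64 ≈ 0.016 while tied or
zero-difference configurations produce values off the k/64 lattice.
Benjamini–Hochberg adjustment is applied within each seven-comparison
family (statsmodels' step-up), and significance is flagged at 0.05.  Note
the step-up is not idempotent: re-adjusting adjusted values can raise them
further, so the property tests assert monotonicity and the cap, not a
fixed point.

## Problem sizes and the reduced profile

The canonical configuration uses the full grids above.  The package's own
reduced "fast" profile — 5 CV folds, 150 trees, mtry {2, 4, 8}, NN sizes
{4, 16} × decay {0, 0.01}, SVM costs {0.25, 2, 32}, 5 PMM chains of 5
iterations — is the profile used by the shipped end-to-end checks and the
reproduction script; on the full 1468-record cohort it completes the
18-scenario × 8-method experiment in a few minutes while selecting the
same order of model complexity as the full grids.

## Known limitations

* Conditional independence (exact mode) or low-order pairwise couplings
  (stochastic mode) cannot represent higher-order interactions a real
  cohort may contain.
* Only the single volume variable is amputed; multivariate and
  non-monotone patterns, and MNAR mechanisms, are out of scope.
* Resubstitution metrics are optimistic in absolute terms; they are used
  comparatively, against a reference computed the same way.
* The MAR ratio is realised up to integer rounding (one cell), which
  matters only at very small allocations.
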