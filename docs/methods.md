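# Methods

This note documents the statistical model, the numerical choices, and the
design decisions behind `priolasso`, in the spirit of a package vignette. It
states no empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## The hierarchical fit

Covariates are partitioned into M blocks and ordered by a user-chosen
priority permutation π. Step m solves an L1-penalized regression of the
outcome on block π_m in which the accumulated linear score of steps
1..m−1 enters the linear predictor as an offset with coefficient fixed to 1.
Supported outcome families and losses:

| family     | loss (per sample)                              | intercept |
|------------|------------------------------------------------|-----------|
| continuous | (1/2n) Σ (y − offset − b0 − xβ)²               | yes       |
| binary     | −(1/n) Bernoulli log-likelihood, logit link    | yes       |
| survival   | −(1/n) Cox partial log-likelihood, Breslow ties| no        |

For a continuous outcome the offset construction is identical to fitting
each block to the running residuals; for the other families it conditions
the block's fit on everything higher-priority blocks already explain. The
final linear predictor is always the sum of *full-data* per-block
contributions, so it decomposes exactly by block and is transportable as a
plain coefficient table.

**Plain vs cross-validated offsets.** The in-sample score η̂ of a step is
over-optimistic about its block's predictive content, which systematically
under-credits later blocks. With `cv_offsets=True` the offset carried to the
next step is computed per sample from fits that excluded that sample's fold
(K = `nfolds_offset`, default 10, event-stratified for survival, its folds
seeded independently of the penalty-selection folds). Each fold's refit
repeats the entire selection procedure — penalty path, fold-internal CV,
per-block cap — on the training complement; for the continuous and binary
families the fold's intercept is part of the carried offset, for Cox the
offset is a pure linear score. Cross-validated offsets change only what
downstream steps condition on; reported coefficients are full-data estimates
in either mode. Whether the penalty should instead be frozen at its
full-data value inside each offset fold is a genuinely open choice; this
package re-estimates it, which keeps every fold fit a faithful miniature of
the full procedure.

**Penalty selection.** The path holds 100 log-spaced penalties from
λ_max (the smallest λ with an all-zero solution, computed from the null-model
gradient including the offset) down to λ_max·10⁻⁴ (10⁻² when p ≥ n). CV
error is squared error / binomial deviance / Cox partial-likelihood deviance
(−2·held-out log PL per held-out sample; the "basic" CV, not the
V&VH difference), with one seeded fold partition shared across the whole
path. `lambda.min` picks the penalty with minimal mean CV error (ties go to
the sparsest, i.e. largest, penalty); `lambda.1se` picks the largest penalty
whose mean error is within one standard error of that minimum. A per-block
cap restricts the choice to penalties whose fit respects the cap; if none
does, the block is fully suppressed, which is legal — an all-zero step simply
passes its offset through. The top-priority block may be fitted unpenalized
(p < n required), via OLS / IRLS-GLM / Newton Cox regression from
numpy/statsmodels.

**Order selection.** `choose_order` scores each candidate permutation by
the 5-fold (default) cross-validated prediction loss of the entire pipeline;
outer folds are seeded separately from all inner folds so no information
leaks from penalty selection into order selection. Ties break by candidate
position.

## The solver

No installed library fits an L1 path with a fixed offset for all three
families, so the per-block primitive is implemented here: cyclic coordinate
descent over an active set with full KKT screening, wrapped in IRLS for the
binary and Cox families (weights and working responses from the diagonal
Hessian of the log-likelihood; probabilities clipped to [10⁻⁵, 1−10⁻⁵],
weights floored at 10⁻⁹). Features are centered and, by default, scaled to
unit variance inside the solver (`standardize=False` disables scaling;
coefficients always return on the original covariate scale). Convergence:
coefficient max-change below 10⁻⁷ per sweep, at most 10⁵ sweeps, at most
200 IRLS iterations. The unit tests pin the solver to closed-form
soft-thresholding, scikit-learn (gaussian, logistic) and scikit-survival's
coxnet (Cox) at matched penalties.

Two safeguards address the near-degenerate deep-penalty regime (tiny λ with
as many parameters as events, reached only at the far end of CV grids on
small folds): the auto-generated path stops early once more than 99% of the
null deviance is explained, and IRLS stops at numerical stationarity of the
penalized objective — keeping the better of the last two iterates — when
coefficients drift along a flat ridge or enter a limit cycle. If the IRLS
budget runs out the last iterate is accepted: extra precision there cannot
change any cross-validation decision. Fold refits inside CV use a reduced
IRLS budget (25) for the same reason. The compiled (numba) kernel and the
pure-Python fallback implement the identical update.

## Validation metrics

All IPCW weights use the Kaplan–Meier estimate Ĝ of the censoring
distribution with the left-limit convention Ĝ(t⁻) for event weights; ties
between event and censoring times count the event first.

* **Uno's C** — over pairs (i, j) with an event for i before min(τ, T_j),
  weight Ĝ(T_i⁻)⁻²; score ties count ½. τ defaults to the last event time.
* **Brier / IBS** — BS(t) averages Ŝ(t)²/Ĝ(T⁻) over observed events by t and
  (1−Ŝ(t))²/Ĝ(t) over subjects still at risk; IBS = (1/t_max)∫₀^{t_max} BS
  by trapezoid on the evaluation grid. Two horizons are reported: the
  clinical horizon (default 2 time units) and the last validation event.
* **Calibration slope / optimism** — Cox coefficient of the score as sole
  covariate (lifelines, Newton precision 10⁻¹⁰ so the training-data identity
  slope = 1 of an unpenalized model holds to ~10⁻⁸); optimism =
  slope_train − slope_validation.
* **Risk groups** — exhaustive search over ordered pairs of candidate
  cutpoints (midpoints between consecutive distinct training scores)
  maximizing the 3-group logrank χ², each group ≥ 10% of the sample
  (unconstrained maximal selection degenerates to tiny extreme groups; the
  10% floor is this package's choice). Ties break to the most balanced
  group sizes, then the smaller first cutpoint. The scan uses an O(n²)
  cumulative formulation and is checked against brute-force evaluation of an
  independent logrank implementation. Note that maximally selected groups
  are optimistically separated on the data that chose them; the hazard
  ratios reported by `external_validation` therefore come from the
  *validation* cohort with cutpoints frozen on training data.
* **Group hazard ratios** — unpenalized Cox on low/high indicators with the
  intermediate group as baseline; Wald 95% CIs; likelihood-ratio test
  against the null model.
* **2-year TPR/TNR/AUC** — cases are observed events by the horizon,
  controls are subjects under observation past it, subjects censored earlier
  are excluded (their status is unknown); the cutoff is the median score of
  the evaluated cohort. An IPCW time-dependent AUC (`ipcw_auc_at`, via
  scikit-survival) is available as a sensitivity variant; the complete-case
  AUC is the default.
* **Survival curves** — Breslow baseline hazard from the training scores
  (shared-denominator tie handling), individual curves
  S(t|x) = exp(−H₀(t)e^score) as right-continuous step functions, averaged
  within risk groups for the observed-vs-predicted comparison.

## The synthetic generator

The generator is the package's test bed, with an explicit statistical
contract: L latent standard-normal factors drive all blocks through
per-block loading matrices, plus independent feature noise; continuous
features are scaled to unit variance, binary features are thresholded at a
target prevalence (default 0.3). Overlap between two blocks' loading
patterns is the redundancy dial — identical loadings make their signal
subspaces nearly collinear, the regime the priority hierarchy is designed to
arbitrate. The outcome comes from a sparse true linear predictor:
Gaussian noise (variance set directly or via a target signal-to-noise
ratio) for continuous outcomes, a logistic link for binary ones, and an
exponential (optionally Weibull) hazard h₀·e^η for survival, with
independent uniform-window censoring whose upper bound is calibrated by
bisection on the realized sample to hit the target censoring fraction.

`aml_like_preset(scale)` mirrors the shape of a typical AML multi-omics
study: blocks of 2 (prioritized score), 8 (clinical), 40 (binary mutations)
and round(15809·scale) (expression) features, six factors with the
score/clinical pair sharing three of them and the mutation/expression pair
the other three, sparse direct effects in every block (2/4/5/10 features at
magnitudes 0.5/0.3/0.4/0.2), baseline hazard 0.2 and 50% censoring. These
values are fixed once as a realistic mid-signal regime — strong enough that
discrimination is clearly above chance at n ≈ 450, weak enough that penalty
selection matters. The tests and the acceptance script run at scale 0.005
(79 expression features) with n = 447 training / 250 validation samples,
sizes chosen so the full four-scenario sweep completes in minutes on one
CPU.

What the generator does **not** emulate: heavy-tailed expression marginals,
batch effects, informative censoring, block-wise missingness. Passing tests
therefore demonstrate the correctness and the qualitative behavior of the
procedure (redundancy absorption, the effect of cross-validated offsets,
calibration identities), not its performance on real cohorts.

## Known limitations

* Blocks missing for a subset of patients are not handled; every sample
  needs every feature (missing values are rejected at load time, never
  imputed).
* Only the plain L1 penalty is offered — no elastic-net mixing, adaptive
  weights or stability selection.
* Cox fitting assumes Breslow tie handling throughout; datasets with heavy
  ties may prefer Efron's correction, which is not implemented.
* The maximal-logrank stratification is a training-data construct; its χ² is
  not a valid test statistic without resampling corrections.
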