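# Methods

## Scope and data model

`bipanel` models monthly product-level drug expenditure ("budget impact",
BI: list price × volume, euros) on a national sales panel.  Each product
has a profile of launch-time covariates — tumor site, molecule type,
orphan designation, a single combined flag for conditional approval or
approval under exceptional circumstances (CE), and FDA first-in-class
status (FiC) — and a run of consecutive monthly BI records indexed
t = 1, 2, … from its first record.  Month indexing is product-relative and
gap-free by invariant, so time transforms √t and t^p are defined and
positive, and calendar arithmetic is done in whole year-month units.
Products in the panel without a covariate row are rejected, not imputed:
the covariates are required model inputs.

A cohort split assigns whole products by first-record date: first record
on/after the split month → validation, earlier → training.  A horizon
`t_max` truncates every product to its first `t_max` records (45 in the
main design, 42 in the robustness run), because that is the period the
method aims to predict.

## The mixed model

For product i with n_i monthly records,

    y_i = X_i β + Z_i b_i + ε_i,     y = log BI,
    Z_i = [1, t],  b_i ~ N(0, G),    ε_i ~ N(0, σ² R_i(φ)),
    R_i(φ)[a,b] = φ^|a−b|  (AR(1) in month index).

The random structure (per-product intercept + time slope) and the AR(1)
correlation are fixed by design; only the fixed effects vary.  Fixed-effect
terms are (covariate, time-transform) pairs: a transform of "none" is a
main effect, anything else is the covariate indicator × f(t) with
f ∈ {√t, t, t², …, t⁶}; the linear time main effect is its own term; at
most one time interaction per covariate.  Categorical covariates are
dummy-coded against the lexicographically smallest level of a registry
frozen from the **full** covariate table, so design columns are identical
across refits on panel subsets.  A level unseen at prediction time maps to
the reference level with a warning — prediction must not fail mid-run.
Design columns with no support in a given training subset (an absent
categorical level) are dropped from that fit and reported with
coefficient 0.

### Estimation

Maximum likelihood, not REML: forward stepwise selection compares AICs of
models with different fixed effects, which is invalid under REML.  β is
profiled out by GLS given the variance parameters (G, σ², φ), which are
optimised by L-BFGS-B on unconstrained transforms: Cholesky factor of G
with log diagonal, log σ², atanh φ.  Starting values are fixed for
determinism: the OLS residual variance, G = 0.1·I, φ = 0; convergence
tolerance 1e-8 on the relative change of −ℓ, at most 500 iterations;
failures return a result flagged `converged=False`, never silently.
Because every product's months are the prefix 1..n_i, the marginal
covariance V_i = Z G Z' + σ² R_i depends only on n_i, so one Cholesky per
distinct series length serves all products of that length — fits on
200 × 45 panels take well under a second.

AIC = 2k − 2ℓ with k = p + 5: the p fixed coefficients plus three
parameters of G, σ² and φ.  Stated explicitly because AIC parameter-count
conventions differ.

### Prediction

Predicted log BI is the conditional mean given the product's random
effects when the product contributed data to the fit — x'β̂ + b̂0 + b̂1·t
with the BLUP b̂_i = G Z_i' V_i⁻¹ (y_i − X_i β̂) — and the population mean
x'β̂ otherwise (t_data = 0).  Predictions are **marginal over the AR(1)
residual**: the estimated residual autocorrelation describes the
within-product noise but is not used to forecast future residuals, which
mirrors the prediction behaviour of the standard mixed-model software
class this design follows.  Euro-scale predictions are the naive
exponential exp(ŷ) with no smearing correction; this is a known source of
downward bias (E exp(y) > exp(E y)) and is deliberate, keeping predictions
directly comparable to observed euros.

## Stepwise selection

From an intercept-only model, each step fits the current structure plus
every admissible candidate.  Candidates are ranked by AIC; the best-AIC
candidate is accepted only if its AIC strictly improves the current model
and its p-value is below 0.10; if it fails the p-gate the next-best
candidate is considered.  AIC ties within 1e-6 break by enumeration order,
making selection bit-reproducible.  The default gate is a Wald test
(joint chi-square across a multi-level term's columns); a likelihood-ratio
gate is available via `use_lr=True` since the original convention is not
determinable.  Main effects of accepted interactions are not forced in —
predictor choice is purely predictive, and forcing main effects inflates
the parameter count.  Candidate fits that fail are skipped with a warning.
The time main effect is offered as an ordinary candidate rather than
forced, since the final structure can earn it on its own.

## Rolling-forecasting-origin validation

Per validation product k and t_data ∈ [0, min(t_max − 1, months of k)]:

* t_split = first record month of k + t_data;
* training set = every training-pool product's records with calendar month
  strictly before t_split (each product capped at its first t_max records
  — both cutoffs applied jointly) plus the first t_data records of k;
* the model is refit (same structure) and t_pred ∈ [t_data + 1, t_max] of
  k is predicted; cells are emitted for every t_pred, with observed BI
  attached where k has a record.

The structure is selected once per horizon on the initial training cohort
and held fixed across cycles; coefficients are re-estimated every cycle.
Cycles whose refit fails are excluded from metrics with a logged count
(> 5% failures triggers a run-level warning).  A construction audit
records, per cycle, exactly which months of which products were trained
on; the test suite asserts no leakage (nothing of k beyond t_data, nothing
of others on/after t_split or beyond t_max) on every cycle.

Caps: predictions (never observations — real panels contain months below
any floor) are clamped to [€5 000, 2 × max monthly BI of the total
dataset], the ceiling computed once per run.  The dual-horizon run repeats
selection + validation at t_max = 45 and 42 and averages the two capped
euro predictions per (k, t_data, t_pred) where both exist ("absolute"
predictions are positive, so the average is taken directly); averaging
happens after capping in each run.  Scenario analyses re-derive
predictions from the stored raw values under four regimes: both caps,
min-only, max-only, none.

## Error metrics

* Symmetric error ratio (per sample with observed BI):
  error = exp(|ln(observed/predicted)|) = max(o, p)/min(o, p) ≥ 1.  The
  max/min form makes the over/under symmetry exact in floating point.
* Signed percentage difference (predicted − observed)/observed × 100, and
  band fractions |pct| ≤ 40 and ≤ 100 (closed bands).
* Aggregation: per (t_pred, t_data), per t_data, or none; each summary
  reports n, mean, sd (0 for singletons), median, IQR as the single width
  p75 − p25, and the 5/25/75/95 percentiles with linear interpolation
  between order statistics (the convention must be fixed somewhere; this
  is numpy's default and is documented here).
* Tests: one-sample t-test of mean ln(observed/predicted) against 0;
  exact binomial test of P(underprediction) against ½, where
  underprediction ⇔ ln ratio > 0 and exact ties are excluded (logged);
  OLS of the raw error ratio on t_data over individual samples
  (`slope_on_log=True` switches to the log ratio).

## Synthetic cohorts

The generative model is exactly the estimator's data-generating process:
covariates drawn independently per product from configured prevalences,
(b0, b1) bivariate normal, stationary AR(1) residuals with marginal
variance σ² and innovation variance σ²(1 − φ²), log-linear fixed effects,
euros by exponentiation (right-skewed by construction) stored at 2
decimals (tests tolerate the quantisation; `round_eur=False` gives the
machine-precision noise-free limit).  Same config + seed ⇒ identical
panel.

`paperlike_config()` reproduces the geometry of the oncology study design
this package is built around: 25 products launching 2005-01…2012-04
(training under a 2012-05 split) and 44 launching 2012-05…2016-06
(validation), 6–45 months each censored at the 2017-09 panel end, and the
study's final fixed-effect structure (time, time × CE, molecule type,
√t × {orphan, FiC, tumor site}).  Launch counts per window are fixed, not
sampled, so split sizes are deterministic.  The study reports no
distributional parameters of the real data, so euro level (e^10.5 ≈ €36k
median launch month), effect sizes (±0.2–0.8 log units), var(b0) = 1.0,
var(b1) = 0.004, σ² = 0.25 and φ = 0.6 are package choices: they produce
month-45 spreads of roughly two orders of magnitude across products,
which is the qualitative picture of oncology launches.  Four tumor sites
and three molecule classes keep categorical cells populated at desk
scale.

What the generator does **not** emulate: indication extensions, price
cuts and reimbursement shocks, patent expiry, correlated covariates
(orphan/CE/FiC are independent here), calendar-time market trends, and
any heavy-tailed noise beyond log-normality.  A green validation on
synthetic cohorts therefore establishes that the pipeline is correct and
self-consistent (parameters recoverable, no leakage, errors shrink as
t_data grows) — not that real drug expenditure follows this model.

## Numerical and degenerate-input choices

* Optimiser bounds keep exp/atanh transforms finite (log-sd ∈ [−10, 10],
  log σ² ∈ [−30, 30], atanh φ ∈ [−7, 7], i.e. |φ| ≤ 0.999998).
* Non-PD marginal covariance raises an estimation error naming the first
  affected product; a singular GLS normal matrix falls back to
  least-squares with pseudo-inverse standard errors.
* A model needs more observations than coefficients and at least one
  product; single-observation panels raise.
* Empty cohort sides after a split warn rather than fail.
* Reporting on zero cells, or on cells with no observed months, raises
  before any file is written.

## Known limitations

* Naive exponentiation biases euro predictions downward (no smearing
  correction); the symmetric error metric partially absorbs this.
* ML variance components carry the usual O(p/N) downward bias relative to
  REML; immaterial at the tested cohort sizes.
* The rolling validation refits one model per (product, t_data) cycle;
  cost grows as |A| × t_max × fit cost.  Cycles are independent and may
  be computed in any order with identical results, but no parallel
  executor is shipped.
* The per-t_data median error stabilises ("plateaus") only where t_data
  groups hold enough samples; on small cohorts the high-t_data medians
  rest on a handful of observations and remain noisy.
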