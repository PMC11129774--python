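# Methods

## Problem and scope

`qualinear` models a numeric response (a treatment-effectiveness score) on
one or more numeric predictors (age) and one or more categorical predictors
(treatment arm). The categorical variables are brought into the linear
model by reference-cell dummy coding; estimation robustness is addressed by
a case-resampling bootstrap; uncertainty in the qualitative structure is
expressed by a possibilistic fuzzy regression; and a small feedforward
network provides an independent check that the chosen predictor set carries
the signal.

## Dummy coding

A variable with α observed levels produces α−1 indicator columns named
`<variable>_<level>`. The reference level — user-specified, defaulting to
the last level in lexicographic order, a deterministic rule that picks C
for arms A/B/C — maps to the all-zero row, so its effect is absorbed by the
intercept and each indicator coefficient is a contrast against it.
`response_function_decomposition` returns the per-level effective
intercepts (β₀ for the reference, β₀+β_k otherwise) together with the
shared slopes. Unseen levels at transform time raise an error rather than
silently coding as all-zeros, which would alias the reference level.
Missing values abort validation; no imputation is attempted.

## Bootstrap and splitting

The bootstrap draws whole cases uniformly with replacement (default size
10000), and the pseudo-sample is then split 70:30 (train size
`round(0.70·n)`, banker's rounding by default to match the R runtime's
`round`; floor available). Because the bootstrap precedes the split,
duplicated cases appear on both sides of the partition; this mirrors the
procedure being reimplemented and is the default. The
`split_before_bootstrap` flag gives the leakage-free order: partition the
original cases first, then bootstrap each side separately to the same
target sizes.

All randomness flows from one root seed through named substreams
(`bootstrap`, `split-lm`, `split-nn`, `nn-init`, `synthetic`), implemented
as `SeedSequence` spawn keys, because the regression split and the network
split are independent draws in the original procedure. A report is
therefore reproducible from its provenance block alone.

## Ordinary least squares

Coefficients are computed from a thin QR factorization (never an explicit
inverse); the covariance is σ̂²R⁻¹R⁻ᵀ. Rank deficiency is declared when the
singular-value ratio falls below 1e-10, and the offending columns are named
via pivoted QR — the classic failure is including all α indicators plus the
intercept. Inference: t = β̂/SE, two-sided Student-t p-values on n−p−1 df,
R² and adjusted R² in their standard centered forms. The test suite checks
the solver against an explicit normal-equation oracle and against
statsmodels OLS (cross-check only; statsmodels is not a dependency of the
implementation).

## Possibilistic fuzzy regression

The estimator is deliberately canonical rather than a port of any specific
R package: centers by OLS, then minimum-total-vagueness spreads by linear
programming (HiGHS via `scipy.optimize.linprog`), with the inclusion
constraints and objective stated in the README. Design choices:

- **Asymmetric spreads.** Each coefficient carries separate left/right
  spreads; the symmetric single-vagueness form is the special case
  s^L = s^R. Asymmetric supports are what fitted boundary tables for this
  kind of data actually show.
- **Sign handling.** |x_ij| appears in both the objective and the spread
  terms (the standard Tanaka convention), so signed regressors keep
  lower ≤ central ≤ upper; for the non-negative regressors of the worked
  example this reduces to substituting coefficient endpoints.
- **h-level.** Default 0 (the most permissive support); the LP objective is
  non-decreasing in h, and h = 1 is excluded as degenerate.
- **No outlier trimming.** Some published spread-fitting variants trim
  extreme cases before fitting the support; here every training case
  constrains it. Consequently the fitted centers equal OLS exactly, and the
  fuzzy central predictions coincide with the linear-model predictions on
  the same training split — fitted boundary tables produced by trimming
  variants will differ accordingly.
- **Feasibility.** The LP is always feasible (intercept spreads alone can
  cover any residual), so solver failure raises rather than being handled.

Predictions return ⟨central, lower, upper⟩ with the support evaluated at
the full spreads; all training responses lie inside their supports by
construction, which the tests assert to 1e-9.

## Network validator

Architecture fixed at inputs → 3 → 2 → 1 with logistic hidden units and a
linear output. All columns are min-max scaled to [0,1] (fit on the full
bootstrapped table before the network split, as in the original procedure;
`scale_on_train_only` refits on the training part and clips the test side
into [0,1]). Weights and biases initialize uniform(−0.5, 0.5) from the
seeded stream.

Training is full-batch gradient descent on the mean squared error.
Defaults: learning rate 0.5, at most 2000 epochs, stopping when the
gradient norm on the summed-squared-error scale (n times the mean-scale
norm) drops below 0.01 — the scale on which that threshold conventionally
signals convergence. The learning rate was chosen by probing the
[0,1]-scaled regime: 0.05 stalls near the response variance within the
epoch budget (no better than predicting the mean), 0.2 is seed-sensitive on
the identity-map check, 0.5 converges on all probed seeds, and 1.0
diverges. Divergence (non-finite loss) raises with advice to lower the
rate. Backpropagation gradients are verified against central finite
differences to 1e-6 relative error.

The reported `MSE net` is on the scaled response and is therefore *not*
unit-comparable with the raw-scale regression MSE; the comparison table
says so explicitly, and a back-transformed variant is emitted alongside.
The published prediction step feeds the response column into the network
together with the covariates; that is treated as an erratum — this package
always feeds exactly the covariate columns.

## Synthetic data

The generator emulates the worked example's structure: integer ages uniform
on 19..67, treatment labels categorical (uniform over A/B/C by default),
and

    effectiveness = 7.948 + 0.919·age + {A: 25.075, B: 8.013, C: 0} + N(0, 2)

with all parameters configurable. The default coefficients are the worked
example's fitted values and the noise standard deviation of 2 gives
residual scatter realistic for an effectiveness score spanning roughly
25–70 points; n defaults to 24 cases. What the generator does **not**
emulate: age–treatment dependence, non-Gaussian or heteroscedastic noise,
and measurement rounding of the response. Passing tests on this synthetic
world therefore demonstrate correctness of the estimators and their
calibration under the assumed model, not robustness to real-data
violations of it.

## Numerical conventions

- Rank-deficiency threshold 1e-10 on the singular-value ratio.
- LP solved by HiGHS; returned spreads are clipped at 0 to remove solver
  round-off of order 1e-12.
- Train size rounding: banker's by default, floor optional; both sides of a
  split are forced non-empty whenever n ≥ 2.
- Comparison-table averages are always recomputed from their columns; a
  caller-supplied summary row that disagrees triggers a warning (published
  tables occasionally transpose such averages).
- Report serialization uses fixed float formats and sorted JSON keys so
  identical seeds give byte-identical artifacts.

## Known limitations

- The fuzzy estimator is possibilistic only: crisp inputs and output, no
  fuzzy least squares, no h-level defuzzification indices, no inference on
  the fuzzy coefficients.
- The bootstrap is plain case resampling; no stratification or BCa
  intervals.
- The network has no regularization or minibatching and is not intended as
  a competitive predictor; it exists to validate the variable set.
- With bootstrap-before-split (the faithful default), test cases duplicate
  training cases, so held-out error estimates are optimistic; use
  `split_before_bootstrap` for honest generalization error.

## Problem sizes used in the shipped checks

The test suite exercises the pipeline at bootstrap sizes in the hundreds to
thousands and the documented example at the full 10000; oracle comparisons
for the spread LP run exhaustive vertex enumeration on instances up to
n = 8 cases and p = 2 predictors, where enumeration is exact and fast; the
parameter-recovery study uses 200 replicates of n = 2000 cases. These sizes
make every check exact or statistically well-powered while keeping the
whole suite comfortably fast.
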