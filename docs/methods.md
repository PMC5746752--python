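# Methods

## Scope and model

`dsdpower` assesses the criticality of process parameters (PPs) studied in a
screening DoE against a critical quality attribute (CQA) with a one-sided
specification. The response model is ordinary multiple linear regression in
coded units,

    y = b0 + X b + e,      X in R^(n x p),

where each factor's screening range is mapped to [-1, +1]. Normal operating
ranges (NORs) live on the same coded scale and may extend beyond the
screened range. All physical-to-coded mapping is the caller's
responsibility; the package never sees physical units.

Criticality is defined against a *threshold*: either given directly for the
studied intermediate stage, or back-calculated from the drug-substance upper
specification limit through the product of the mean specific clearances of
all downstream unit operations (`threshold_from_usl`). Clearance factors
must be positive; the product is order-invariant. Only upper-sided
specifications occur in the bundled presets; the `lower` direction is
implemented by sign symmetry and unit-tested.

## Critical gap and critical effects

* Before experiments: `CG = threshold - mean(y at set point)`.
* After experiments: `CG = threshold - max_{x in NOR box} yhat(x)` for the
  selected model (minimum for lower-sided CQAs).

A non-positive gap raises `ThresholdExceededError` rather than being
clamped: the workflow's premise — a margin to protect — is absent, and that
must surface, not average away.

The critical effect of parameter i under weight w_i is

    beta_crit_i = w_i * CG / max(NORU_i - sp_i, sp_i - NORL_i).

Dividing by the *longest* excursion from the set point is the conservative
choice for asymmetric NORs: the slope only needs to consume the gap at the
farthest admissible setting. Injected critical effects take the sign that
moves predictions toward the threshold (positive for upper-sided CQAs); the
formula defines magnitude only.

**Worst-case prediction.** For additive models (mains + pure quadratics)
the NOR-box optimum separates per coordinate and is solved in closed form
(endpoints plus the interior vertex of a quadratic). With interaction terms
the surface is quadratic along every coordinate, so exact coordinate ascent
is run from all 2^p box vertices plus the midpoint — deterministic, and
verified against a dense grid oracle in the tests for the factor counts of
screening designs (p <= 8). Coordinates the model does not use are reported
at the NOR midpoint.

## Weight grid

With p parameters there are infinitely many effect combinations that just
consume the gap. The grid assigns one parameter a fraction `a` in
{0.01, 0.02, ..., 1.00} and splits the remainder evenly over the others,
for each parameter in turn: C = 100·p combinations, each summing to 1,
ordered parameter-major with `a` ascending. `a = 0` is excluded — it is
uninformative for the indexed parameter and keeps C exactly 100·p. For
p = 1 the only admissible vector (1,) is repeated so the row count
convention holds; the mean then reduces to the fixed-effect power.

## A priori power

Given the set-point replicate noise sigma_SP, the expected residual sum of
squares of the n-run DoE is `SSres = (n-1) * sigma_SP^2`. For each weight
combination, the noiseless response `ytilde = X beta_crit` gives
`SStot = sum (ytilde_i - mean)^2`, an expected coefficient of determination
`R2 = 1 - SSres/SStot`, Cohen's effect size `f2 = R2/(1-R2)`, noncentrality
`lambda = f2 * nu` with `nu = n - p - 1`, and the overall-model F-test
power `1 - F_nc(F_crit | u=p, nu, lambda)` at `F_crit = F^-1(1-alpha)`.
Uncertainty in lambda is propagated by chi-square percentile scaling,
`lambda_low/upp = lambda * chi2_{alpha, 1-alpha}(nu) / nu`, giving a power
interval per combination. The design's a priori power is the arithmetic
mean over all C combinations.

Numerical conventions worth knowing:

* `R2 = 1 - SSres/SStot` can go negative when noise exceeds the critical
  signal; lambda is then clamped to 0, the power floors at exactly alpha
  (central F), and the result is flagged. The conventional definition
  `SStot/(SStot+SSres)` is available via `conventional_r2=True`.
* Because SStot comes from the noiseless critical response only, adding
  replicate center runs *raises the noise charge* `(n-1) sigma_SP^2` without
  adding signal — expected power can decrease. Power is monotone in n when
  the added runs carry signal (e.g. replicating the design); the test suite
  pins both behaviours.
* `n` in the SSres formula is the DoE run count, not the set-point replicate
  count: the expected residual sum of squares must live on the DoE's scale
  to be comparable with SStot.
* u = p (all main effects) regardless of which weights are zero, matching
  the screening-stage sparsity argument that only main-effect power is
  assessed.

## Stepwise model selection

Candidates are main effects, pure quadratics of numeric factors (a 2-level
categorical factor has no curvature), and optionally pairwise interactions,
in that fixed order. From the intercept-only model: enter the candidate
with the smallest partial p-value (two-sided t test of its coefficient in
the augmented model) if p < 0.05, ties broken by candidate order; then drop
the included term with the largest p-value if p > 0.10; iterate to a fixed
point (guarded at 50 cycles). A candidate is skipped with a trace notice if
it would be collinear with the current model or leave fewer than 2 residual
degrees of freedom; entry also stops when the fit is numerically perfect
(zero residual SS makes p-values floating-point noise). Effect heredity is
not enforced: a quadratic may enter without its main effect.

The residual standard deviation `sigma_residuals` uses raw residuals with
denominator sqrt(n-1); the model-df alternative sqrt(SSE/(n-q-1)) is
available as `residual_sd("df")`. The diagnostic ratio
`sigma_residuals / sigma_SP` well above 1 is the signature of an experiment
noisier than its pre-experiment estimate.

## Retrospective power by permutation

For every weight combination c over the *non-significant* factors (a factor
is "significant" if any selected term involves it — a selected quadratic
covers its factor, since its worst-case influence is already modelled):

1. `beta_crit(c)` from the worst-case CG and the current NORs;
2. permute the model residuals uniformly at random;
3. synthesize `y* = b0 + beta_s' X_s + beta_crit(c)' Z + R*`, Z being the
   main-effect columns of the non-significant factors;
4. one OLS refit on `[1 | X_s | Z]` (not a re-run of stepwise — a single
   deterministic fit makes the test well-defined and tractable) and record
   two-sided significance of each injected coefficient at alpha.

A parameter's retrospective power is the fraction of significant outcomes
over all combinations and iterations. Defaults: 1000 permutations per
combination (`combination_strategy="per_combination"`); a `"sampled"`
strategy draws one combination per iteration for quick looks. One seeded
generator drives all permutations in fixed combination order
(parameter-major, `a` ascending), so results are bit-reproducible and a
NOR scan at shrink fraction 0 reproduces the baseline exactly.

The inner loop exploits that the injected effects and the refitted base
model lie in the column space of the full design: across permutations only
the residual vector varies, so the QR factorization, coefficient extraction
rows and coefficient variances are computed once and all permutations are
tested as one matrix product. The batched path is cross-checked against
statsmodels/closed-form OLS in the tests, and the permutation power is
checked against a fully parametric Monte-Carlo oracle (agreement within
0.05) and against the nominal alpha at zero injected effect.

**NOR scans.** `nor_scan` shrinks one factor's NOR symmetrically about its
set point (both arms scaled by 1 - fraction) and re-runs the assessment
under the same seed policy. Two distinct mechanisms, both pinned by tests:
tightening a non-significant factor scales only its own critical effect
(halving the NOR exactly doubles it; other parameters' powers are
unchanged); tightening a factor in the model pulls the worst-case
prediction in, enlarging CG and weakly raising *every* non-significant
parameter's power.

## Synthetic studies

`simulate_study` draws `y = b0 + X beta_true + e` with Gaussian residuals
(or scaled Student-t, df=3, to exercise the permutation test's freedom from
normality) and independent set-point replicates `N(y(x_SP), sigma_SP^2)`,
6 replicates by default — a typical small-scale set-point bracket.

Two presets span the regimes that matter:

* `cc1_like_scenario()` — five chromatography factors, 13-run DSD,
  asymmetric NORs (end pooling [-1.1, 0], elution strength [-1.1, 0.65],
  wash strength [-1.1, 1.1], column loading density [-0.51, 1.1],
  pH [-0.55, 0.55]; set points at NOR midpoints), set-point mean 0.4
  against threshold 1.0, sigma_SP = 0.05 and
  sigma_resid = 7.79 * sigma_SP: the *inflated-noise* regime where a priori
  power is 1 but retrospective power collapses.
* `pr_like_scenario()` — four precipitation factors, 11 runs (9-run DSD +
  two center replicates), NORs temperature [-1.71, 0.41], time
  [0.33, 0.41], mixing [-0.95, 0.95], pH [-0.61, 0.61],
  sigma_resid = sigma_SP = 0.01: the *matched-noise, high-SNR* regime
  (CG ~ 60 sigma_resid) in which retrospective power stays near 1 for every
  parameter. The real study's mixing factor is categorical; a generated DSD
  gives every factor a mid level, so the preset codes it numerically —
  categorical handling (levels strictly +-1, no quadratic) is exercised on
  hand-built designs in the tests.

What the generator does **not** emulate: non-linear responses outside the
quadratic model class, run-order or block effects, heteroscedastic
analytics, and operator-to-operator structure in the set-point replicates.
Passing tests therefore demonstrate the statistical machinery under the
stated model, not robustness to those real-data features — with the partial
exception of the heavy-tailed residual mode.

Note that a per-parameter retrospective power of exactly 1.0 is not
attainable even noise-free: the mean over the weight grid always contains
combinations where the parameter carries a vanishing share of the gap and
detection reverts to the alpha level. "Near 1" (>= 0.95) is the practical
reading of full power.

## Designs

`generate_dsd(m)` builds definitive screening designs for m = 4..8 from
Paley conference matrices C (order 4, 6, 8; the construction asserts
C'C = (order-1) I): the design is `[C; -C; 0]`. Even m gives 2m+1 runs with
one factor at its mid level per non-center run. Odd m uses the (m+1)-factor
design with one column dropped — 2m+3 runs, of which one fold-over pair has
no mid level. (Dropping that pair as well is tempting but provably yields a
singular main-effect matrix: any principal submatrix of a conference matrix
obtained by deleting index k has determinant proportional to C_kk = 0.)
Main-effect columns are exactly orthogonal for every supported m; mirror
closure and single-center-run structure are audited in the tests. Split-plot,
blocked and mixture designs are out of scope.

## Workflow calls and defaults

`assess_cqa` labels each parameter: `critical_significant` (in the model),
`non_critical_powered` (retrospective power >= cutoff, default 0.8,
commonly raised to 0.9), else `potentially_overlooked` with the three
mitigation routes enumerated (re-measure with lower analytical variance,
re-run experiments, tighten the NOR). The workflow never applies a
mitigation automatically — feasibility is an engineering decision — and the
whole report is a pure function of (inputs, configuration, seed).

## Problem sizes

Defaults reproduce the full methodology: 100 weight steps (C = 100·p) and
1000 permutations per combination; a five-factor assessment is a few
hundred thousand batched refits and runs in about a second. The test suite
uses reduced grids (5–20 steps, 200–600 iterations) for breadth and full
fidelity where a tolerance demands it (10^4 iterations for the calibration
check); `scripts/acceptance.py` runs everything at the full defaults.

## Known limitations

* The a priori and retrospective estimands differ structurally (overall-F
  vs per-parameter-t, mean over the same grid): even at matched noise the
  two agree only in the high-SNR regime, and the retrospective mean is
  bounded below 1 as noted above.
* Retrospective power for interaction effects is not assessed (Z contains
  main-effect columns only), mirroring the screening-stage sparsity
  argument.
* Permutation iterations are Monte-Carlo draws; exhaustive enumeration of
  n! permutations is neither feasible at n = 13 nor implemented.
* When the selected model's worst-case prediction already crosses the
  threshold, the assessment is undefined by design and raises; the caller
  decides whether that reflects a real process risk or an over-fitted
  screening model.
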