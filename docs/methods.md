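# Methods

## Model

Grain yield *y* (t ha⁻¹ at 85% dry matter) responds to applied nitrogen
*N* (kg N ha⁻¹) through the linear-plus-exponential (LEXP) function

    y = a + b·rᴺ + c·N ,    0 < r < 1 .

All fitting is done on square-root-transformed yields, because the
variance of plot yields grows with N rate; the sqrt scale stabilizes it
well enough for ordinary least squares. On that scale *a* is the
asymptote-related intercept (sqrt(t ha⁻¹)), *b* (typically negative) the
amplitude of the below-optimum response, *c* the linear supra-optimal
slope per kg N ha⁻¹ and *r* the dimensionless curvature (fitted values in
long-term cereal data sit near 0.985–0.989). The curve's value at N = 0
is exactly *a* + *b*; with *c* < 0 and *b* < 0 it has the interior
maximizer N\* = ln(−c/(b·ln r))/ln r. Note a units subtlety: *c* is
dimensionally sqrt(t ha⁻¹) per kg N ha⁻¹ on the fitting scale, although
response-curve literature sometimes labels it t ha⁻¹.

Predictions are squared back to t ha⁻¹, so all reported yields are
nonnegative by construction.

## Fitting

For fixed *r* the LEXP model — including per-group (per-year,
per-treatment) *a*, *b*, *c* coefficients — is linear in all
coefficients. `fit_lexp` therefore profiles the residual sum of squares
over *r* with an exact inner least-squares solve at each candidate *r*
(bounded one-dimensional minimization over (0.5, 0.9999), convergence
tolerance 1e-10 on *r*), rather than running a joint Gauss–Newton
iteration: the optimum is identical and the profile approach cannot
diverge. Initialization is therefore a non-issue; the search interval is
the only tuning. Standard errors come from the Jacobian-based covariance
σ̂²(JᵀJ)⁻¹ at the optimum, with the ∂/∂r column appended when *r* is
estimated. A group with exactly as many distinct N rates as free
parameters is fitted (zero residual df contribution) but logged; fewer
rates is a singular design and is rejected naming the group. *r* cannot
vary by year when a group has fewer distinct N rates than free
parameters — with four rates the per-year model is rejected and a common
*r* is kept (the barley situation).

## Weather parameterization and selection

Writing *a*, *b*, *c* as linear functions of covariates with *r* fixed
gives a linear model whose design columns are the covariate times 1, rᴺ
and N respectively. The pipeline is:

1. **Season alignment.** Monthly total rainfall (TR) and mean temperature
   (MT) are aligned to the cropping season labelled by harvest year:
   October (of the previous calendar year) through September for winter
   wheat (24 candidate variables), February–September for spring barley
   (16). This is the only place calendar years are shifted.
2. **Screening.** Pearson correlations of annual yield with each
   candidate are computed per N rate (× mineral treatment); candidates
   are ranked by mean absolute correlation across strata, and a greedy
   pass in rank order retains a candidate only if its |ρ| with every
   already-retained candidate is ≤ 0.3. The greedy rule is the minimal
   procedure consistent with keeping, among collinear variables, the
   better-ranked one; the retained set depends on the ranking, so the
   dropped-variable audit trail (variable, trigger, ρ) is always
   exported. The retained set is *not* monotone in the threshold for a
   greedy rule (a variable kept at a low threshold can be displaced at a
   higher one by a newly-retained competitor), so no such property is
   claimed or tested; the invariants that do hold — pairwise |ρ| bound,
   order-invariance, determinism of tie-breaks (rainfall before
   temperature, then earlier month) — are asserted.
3. **Maximal model.** Every retained variable enters the *a*, *b* and *c*
   functions, in screening-rank order; cultivar (and treatment) factors
   use first-level-zero coding; configured variables get a quadratic
   pair "(1)"/"(2)". Quadratics default to orthogonal polynomials over
   the observed values (Forsythe recurrence, the construction behind R's
   `poly`), which keeps temperature-squared coefficients on an O(1)
   scale; a raw-polynomial mode exists for comparing fitted coefficients
   with a raw-basis generating truth. Which variables receive quadratics
   and which interaction families exist (treatment×weather,
   treatment×cultivar, default on *a* only) are configuration choices.
4. **Backward AIC.** AIC = n·ln(RSS/n) + 2(k+1) (only differences
   matter); at each step the droppable term-group whose removal most
   reduces AIC is removed, until no removal reduces it. Droppable groups
   respect a hierarchy: "(2)" before "(1)", interactions before the main
   effects they involve, factor dummy blocks as one unit, intercepts
   never. The AIC trajectory is strictly decreasing by construction and
   asserted.
5. **Partial-F pruning.** Marginal extra-sum-of-squares F-tests
   (F = (ΔRSS/Δdf)/(RSS_full/df_full)) remove, iteratively, the group
   with the largest p ≥ 0.05, under the same hierarchy; on exit every
   remaining droppable group has p < 0.05 (asserted). A joint F-test of
   everything eliminated from the maximal model is reported alongside
   both AICs. The two criteria may disagree; the parsimonious model's
   AIC is reported even when above the AIC-stage minimum.
6. **Outlier years.** Years can be excluded by an explicit list, or
   flagged by a rule: the named covariate exceeds a configurable
   quantile (default 0.98) *and* removing the year flips the sign of the
   fitted quadratic "(2)" coefficient. Exclusions are always logged; by
   default *r* is carried forward from the all-years fit rather than
   re-estimated after exclusions (an option exists).

Elimination loops use a Gram-matrix RSS solver on unit-normalized
columns (Cholesky with a least-squares fallback) for speed; the public
`fit_linear` is exact OLS via statsmodels and tests cross-check the two
against a normal-equations oracle at 1e-10.

## Synthetic data

The generator emulates the structure of two long-running cereal
experiments (1968–2016): a winter-wheat trial with N rates
{0, 48, 96, 144, 192} plus {240, 288} from 1985, six cultivar eras and
two excluded harvest years; and a spring-barley trial with rates
{0, 48, 96, 144} crossed with four mineral treatments (PKNaMg, P, KNaMg,
Nil), nine cultivar eras and one missing treatment-year. Monthly weather
uses normal temperatures and gamma rainfall (nonnegative, right-skewed)
with a Gaussian copula for cross-correlations; the default configuration
resembles a southern-England lowland climate and encodes the negative
June temperature–rainfall association. Yields are generated as
sqrt-scale LEXP values whose *a*, *b*, *c* are shifted linearly (or
quadratically, via coef·(x−center)^degree) by weather and cultivar,
plus Gaussian noise (SD 0.15 on the sqrt scale — a choice that makes
raw-scale spreads resemble long-term plot data; it is not derived from
any published fit), floored at zero and squared. The floor induces the
variance-increases-with-N property automatically. The generator
evaluates the LEXP formula in its own code, deliberately sharing nothing
with the fitter, so the two act as mutual oracles in tests.

Published curve constants are used exactly where they exist (wheat
all-years a = 2.402, b = −1.261, c = 0.00085, r = 0.985; barley
per-treatment c values; PKNaMg a = 2.59, b = −1.33); the remaining
barley a/b baselines are synthetic choices producing flatter, lower
curves in the order PKNaMg > P > KNaMg > Nil.

What the generator does **not** emulate: carry-over of rotated N rates
(plot labels only), autocorrelated or trending weather, CO₂ and soil
fertility trends, pest/disease years, within-year daily weather.
Passing recovery tests on this generator therefore demonstrate that the
pipeline recovers the stated generating structure under clean
assumptions, not that real archives satisfy those assumptions.

## Operating-characteristic experiments

`experiments.term_recovery_experiment` replays the full pipeline
(generate → per-year fits and r̂ → screening → maximal → backward AIC →
partial-F) on 200 replicated 49-year wheat-layout trials whose truth has
one linear (MT May) and one quadratic (MT April) weather effect on *a*
plus a cultivar trend — three weather term columns in the raw basis —
with effect sizes four to six times their maximal-model standard errors.
Two retention metrics are reported:

- **variable level** (each generating effect is represented somewhere in
  the selected model): ≈ 0.92 over 200 replicates, limited mainly by
  chance |ρ| > 0.3 screening collisions at n ≈ 47 years (≈ 3.6% per
  variable pair);
- **strict parameter attribution** (the effect retained on *a*
  specifically): ≈ 0.84. With only 5–7 N rates the columns x·1, x·rᴺ and
  x·N for the same weather variable are strongly collinear, so *which*
  LEXP parameter carries an effect is weakly identified; backward
  elimination sometimes attributes a true *a*-effect to the *b* or *c*
  function. This is a genuine identifiability property of the method at
  these designs, not an implementation artifact, and it is why the
  package reports both metrics.

Conditional on retention, the recovered coefficients are unbiased within
Monte-Carlo error; the linear "(1)" member of the quadratic pair shows a
small (≈ −5%, within 3 MC SEs) downward shift traceable to replicates
where a collinear *b*/*c* twin column survives selection and splits the
signal. The type-I error of the marginal partial-F prune, measured on a
1000-replicate null-term simulation, matches α = 0.05 (the test is exact
under Gaussian noise); the joint validation F p-value is uniform under
the null (KS-checked at 500 replicates).

The experiment's effect sizes and the vertex position of the quadratic
(1.4 SD above the mean April temperature, so the variable carries a
strong linear component and ranks near the top of the screening order)
were set by a priori power analysis of these operating characteristics;
yields in extreme synthetic years can exceed realistic bounds, which is
accepted for this stress configuration and does not occur in the
default presets.

## Numerical choices and degenerate inputs

- Profile search interval (0.5, 0.9999); `xatol` 1e-10 (1e-8 in the
  replicated experiments, where that precision is ample).
- AIC comparisons use a 1e-9 improvement margin to avoid cycling on
  ties; candidate groups are visited in sorted order, so ties resolve
  deterministically.
- Rank-deficient designs are rejected naming the offending columns (QR
  diagnostic at 1e-9 relative).
- Zero-variance covariates: correlations are reported missing and the
  variable is excluded from ranking; a quadratic basis on a
  zero-variance covariate is rejected.
- RSS = 0 (noise-free data) maps to AIC = −∞, which is harmless because
  only AIC differences on the same data are used.
- Back-transformation squares sqrt-scale values, so negative predictions
  cannot occur; sqrt-scale predictions may be negative in extreme
  extrapolation, which the reporting layer flags.

## Known limitations

- Parameter attribution (a vs b vs c) is weakly identified with few N
  rates, as measured above; coefficient tables should be read at the
  level of "which variables matter and in which direction".
- The greedy screen's outcome depends on the correlation ranking; the
  audit trail exposes, but does not resolve, this sensitivity.
- No multiple-testing correction is applied across the many marginal
  F-tests (α = 0.05 throughout), so weak true effects are easily lost
  and occasional false inclusions are expected.
- No mixed-effects, autocorrelated-error or alternative response forms
  (linear-plateau, quadratic, inverse polynomial) are provided.
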