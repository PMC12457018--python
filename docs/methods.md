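# Methods

This note records the models the package implements, the generating
assumptions of the synthetic study, the numerical choices, and what the
test suite does and does not demonstrate about real data.

## Respirometry

Oxygen consumption is recovered from a pull-mode (excurrent-flow) system in
which the metered flow and both gas analysers sit downstream of the animal
chamber.  With dry-corrected flow `FR_dry = flow (BP − WVP)/BP`, the exact
nitrogen-conserving balance is

    VO2 = FR_dry [(FiO2 − FeO2) − FeO2 (FeCO2 − FiCO2)] / (1 − FeO2),

which needs no respiratory-quotient assumption when both gases are
measured; when CO₂ is unavailable the single-gas form
`FR (FiO2 − FeO2)/(1 − FiO2 (1 − RQ))` with a user-supplied RQ is used
instead.  Barometric pressure defaults to 101.325 kPa and is configurable,
since the instrument records water-vapour pressure but not BP.

Baseline correction subtracts, from the whole record, the offset between
the empty-channel segment mean and the nominal incurrent fraction; with two
or more baseline segments the offset is interpolated linearly between
segment midpoints.  RMR is the minimum over all 30-s sliding windows
(stepping one sample; ties go to the earliest window) of mean VO₂ within
the last 10 min before the first alarm, after discarding the first 10 min
of test-channel data for equilibration; the "restless animal" extension is
represented simply by that window rule, whatever the recording length.
Stress statistics are computed per alarm on the closed window
[alarm, alarm + 60 s]: peak = (max VO₂ / resting − 1)·100 and integral =
(trapezoidal mean VO₂ / resting − 1)·100, then averaged over the (up to
two) alarms.  Expressing them as percentage change rather than a pure ratio
is deliberate: the study's transform offsets (9.76 and 25.07, which
positivise negative values) imply the published statistics can be negative,
which a pure ratio cannot; mass cancels in both ratios, so they are
identical whether VO₂ is whole-animal or mass-corrected.

## Birth-date estimation

Age at first capture inverts the fixed female Gompertz curve
`M(a) = 88 exp(−exp(−0.052 (a − 15)))` g, i.e.
`age(M) = ln(ln(88/M))/(−0.052) + 15` days, read this way because it is the
only bracketing that reproduces the published worked value 65 g → 38 days.
The curve itself is taken as fixed and never refitted.  Only animals of at
most 65 g at first capture are eligible; heavier animals raise a distinct,
catchable eligibility error.  Calendar birth dates round the age to whole
days; all analyses use the unrounded numeric day-of-season (origin 1 July).
Coarsened variants replace the day-scale value by the midpoint of 14- or
28-day bins (midpoints, not bin indices, so the variable keeps its units).

## Mixed models

The Gaussian LMM `y = Xb + Σ Z_k u_k + e` is fitted by REML with the
likelihood profiled analytically over `b` and the residual variance,
leaving a 1–2-dimensional optimisation over variance ratios.  The linear
algebra runs through the random-effect cross-products: diagonal for a
single factor, diagonal-plus-small-Schur-complement for two crossed factors
when one is small (prior-test count, ≤ 4 levels), so a fit costs
milliseconds and 10⁵ permutation refits stay practical.  On balanced
one-way designs the REML components equal the classical
expected-mean-squares ANOVA estimators, which the tests verify to 1e-6;
single- and crossed-factor fits are cross-checked against statsmodels
`MixedLM` on shared data.  Wald z p-values are used for component-model
coefficients and d-separation claims (the convention of piecewise SEM);
Monte-Carlo permutation p-values are used where the study used them — the
repeatability and association analyses — with the scheme: repeatability
shuffles individual-identity labels across observations, fixed-effect tests
shuffle the response vector against the intact design, and
`p = (#{extreme} + 1)/(n + 1)`.

The binomial-logit mixed model is fitted by the Laplace approximation with
the random effects profiled at their conditional mode (penalised Newton)
and the outer optimisation running over the fixed effects *and* log
random-effect SDs together, the scheme `glmer` uses at `nAGQ = 1`.  The
distinction matters: evaluating the Laplace objective at the joint
(β, u) mode instead measurably attenuates both the slope and the variance
with two binary observations per individual.  At σ → 0 the fit reduces to
plain logistic regression (verified against statsmodels GLM).  Quasi-complete
separation raises an error naming the offending covariate; in bootstrap and
permutation loops such refits (finite-sample artifacts of the dummy-coded
test factor) are dropped and counted, and the loop fails loudly if more
than half are lost.

Repeatability is `R = σ²_ind/(σ²_ind + σ²_res)` after adjusting for the
number of prior tests (a fixed categorical factor), and for the binary
entry trait the latent-scale `R = σ²_ind/(σ²_ind + π²/3)`; only the latent
scale is implemented for binomial responses.  Confidence intervals come
from a parametric bootstrap (default 1000 refits on data simulated from the
fitted model) because no analytic CI is prescribed for this estimator.

## Path analysis

Each endogenous node of the DAG is fitted by its matching mixed model with
individual identity and prior-test count as random intercepts.  A random
factor must have at least three levels to be estimable; with only two
sessions the prior-test factor is dropped — a two-level "random" session
effect is inseparable from session-aligned covariates such as body mass and
demonstrably miscalibrates the d-separation tests.  Continuous variables
are pre-scaled (z-scored) so Gaussian-response coefficients are
standardized directly; two-level factors (year, age class) are coded −1/+1
and left unscaled; binomial-node slopes are standardized on the latent
scale as `β·sd(x)/sd_latent` with
`sd²_latent = var(Xβ̂) + Σ σ²_u + π²/3`.  Marginal R² is fixed-effect
variance over total (latent-theoretic for the binomial node).

The d-separation basis set contains one claim per non-adjacent variable
pair, conditioned on the union of both variables' parents, tested by adding
the independent variable to the dependent variable's regression.  Pairs
declared as correlated errors (the three-behaviour syndrome — their
residual correlations are reported but never fed into the fit statistic)
and pairs of two exogenous variables (whose mutual association the DAG does
not constrain) are excluded, following the piecewise-SEM convention; an
oracle test checks every claim against a brute-force d-separation
enumeration on all 5-node DAGs.  Global fit is Fisher's
`C = −2 Σ ln pᵢ ~ χ²(2k)`; a saturated model has C = 0, df = 0, p defined
as 1.  Only Fisher's C is implemented — no AIC-style model comparison and
no covariance-based SEM.  The inverted-direction variant swaps the
behaviour ↔ MR edges and the comparison reports whether every birth-date
edge keeps its sign and significance verdict (α = 0.05).

## The synthetic study

The generator draws, per individual, a birth day from a truncated normal
over the breeding window (mid-July–late November, i.e. days 14–143 from
1 July; mean day 78, SD 30), a study year (balanced ±1), and per session an
ambient temperature (25 ± 4 °C), food abundance (12 ± 4 plants per 4 m²)
and test schedule (≈ 6, 8, 20, 22 weeks of age, with mortality-style
Bernoulli dropout, survival 0.85 per later session).  Responses are built
on the analysis scale with total variance budgeted to one,

    1 = β' Σ β + σ²_ind + σ²_res,   σ²_ind/(σ²_ind + σ²_res) = ICC,

so a standardized coefficient estimated downstream is directly comparable
to its generating value.  Default slopes are the published standardized
path coefficients (birth → exploration 0.365, → distance 0.267, → entry
0.448 latent, → RMR 0.240, → integral stress −0.316, → maximum stress
−0.274; temperature → RMR −0.234; year → RMR 0.723; food, age-class,
body-mass and all direct behaviour → MR effects zero).  ICC targets default
to the long-term repeatabilities of the six traits; the short-term entry
value (0.980) is excluded as a generating regime because it implies a
degenerate latent variance (≈ 160).  The behavioural syndrome applies one
correlation matrix (default off-diagonal 0.4 — the study reports the
correlations as significant but not their values) to the three behavioural
individual intercepts and to the Gaussian session residuals.  The binary
entry trait lives on a latent logit scale whose total variance is solved so
that both its latent ICC and its latent standardized slopes hit their
targets.  Raw measurement columns are affine (or exactly
sqrt/log-invertible, for the two stress statistics) images of the analysis
scale, so the pipeline's transform-then-scale step reconstructs the
generated structure without distortion.

Three generator choices keep the generating process identical to the DAG
the analysis assumes, and are worth knowing about:

* Session (habituation) drift defaults to zero.  The DAG has no session
  node; injected drift is absorbed by the session-aligned body-mass trend
  and breaks the d-separation calibration.  Drift is configurable for
  robustness exploration, and the repeatability models keep the prior-test
  fixed factor regardless.
* Individual size heterogeneity (CV 7 %) enters body mass at testing only,
  not at first capture: early juvenile growth is treated as canalized, so
  the shared inverted growth curve stays valid for ageing and the
  birth-date estimation error stays independent of adult mass.
* ICC targets parameterise the variance components *after* fixed effects.
  Measured, unadjusted repeatability of a variable with individual-level
  covariate effects (RMR, via the year contrast) therefore exceeds its
  component-level target — the published repeatability values are
  raw quantities of that kind, so the pipeline's repeatability table is not
  expected to reproduce them numerically under default settings.

Traces are synthesised by passing a piecewise VO₂ profile — resting level,
Poisson activity bouts confined to the equilibration discard, and an
instantaneous-rise/exponential-decay pulse at each alarm — through the
chamber's first-order washout (time constant volume/flow ≈ 86 s at
1 l / 700 ml min⁻¹), using the exact pull-mode steady-state balance with
RQ 0.85, then adding a constant sensor offset (2×10⁻⁴ fractional O₂) and
Gaussian noise (SD 2×10⁻⁵; the study reports no noise figure, so both are
nominal placeholders).  The pulse amplitude is solved so the *measured*
(washout-smoothed) peak matches the session's target; the decay constant is
then chosen to approach the integral target within the shape family's
feasible range, which a single decaying pulse cannot always reach — the
cohort columns, not the traces, are the authoritative stress values, and
the trace round trip is guaranteed for resting level (1 %) and peak (5 %)
only.

## Problem sizes and tolerances

The recovery study behind the acceptance script uses 200 replicate cohorts
of 300 individuals × 2 sessions with no dropout — large enough that the
Monte-Carlo standard error of each mean coefficient is ≈ 0.003, an order
below the ±0.05 acceptance band.  Repeatability recovery uses the study's
short-term design size (56 individuals, ≤ 2 sessions); null calibration
uses 200 replicates of 149-permutation p-values.  Fisher's C calibration
uses 200 replicates of the full RMR path model.  REML variance ratios are
optimised on the log scale (bounded scalar search, or Nelder–Mead with a
zero-variance restart for crossed factors); ratios below 1e-10 are snapped
to zero; GLMM outer optimisation is L-BFGS-B with log-σ bounded in
[−4, 2.5].

## Limitations

* The generator emulates the study's *assumed* structure; passing tests
  show the pipeline is unbiased and calibrated under that structure, not
  that the structure is true of real bush Karoo rats.  Features of real
  data it does not emulate include seasonal coupling between temperature
  and test date, non-Gaussian behavioural residuals, drift in instrument
  calibration, and informative (condition-dependent) dropout.
* Only the model shapes this study needs are implemented: Gaussian or
  binomial-logit responses, at most two crossed random intercepts (the
  second small), no general formula language.
* Laplace ML for paired binary data carries a known downward bias in both
  slope and variance; the latent standardized coefficient is much less
  biased (the two shrinkages largely cancel), which is the quantity the
  analysis reports.
* Trace-derived integral stress values are shape-constrained by the washout
  (see above); pipelines that re-measure MR from traces
  (`process_traces=True`) will reproduce the integral statistic only
  approximately.
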