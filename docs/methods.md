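# Methods

## Scope

`eqmap` predicts EQ-5D-3L preference-based utilities by *response
mapping*: an ordinal regression per questionnaire dimension, converted
to an expected utility through a value set, with direct OLS regression
of the index as the comparator. Everything below describes what the
package computes, the assumptions behind it, and the choices made where
the design was genuinely open.

## Tariff scoring

The EQ-5D-3L has five dimensions (mobility, self-care, usual
activities, pain/discomfort, anxiety/depression) at three levels each,
hence 243 states. The bundled UK time-trade-off value set is an
additive decrement model:

    U(s) = 1 − c·1[any level > 1] − Σ_d δ_{d,level_d} − n3·1[any level = 3]

with c = 0.081, n3 = 0.269 and per-dimension level-2/level-3 decrements
(0.069/0.314, 0.104/0.214, 0.036/0.094, 0.123/0.386, 0.071/0.236 in
questionnaire order). The loader validates the bundled table against
its two published endpoints, U(11111) = 1 and U(33333) = −0.594, and
fails hard on any mismatch, which catches transcription errors in the
data file. Alternative (e.g. non-UK) coefficient tables load from a
flat YAML mapping with keys `constant`, `n3` and `{dimension}_{level}`;
they must satisfy the non-negative-decrement invariant but are not
anchor-checked. Utilities are kept at full float precision; rounding to
3 d.p. happens only in report formatting.

## The partial proportional odds model

For one dimension with response d ∈ {1, 2, 3} and covariate row x:

    P(d ≤ 1) = σ(k₁ − x·β⁽¹⁾),  P(d ≤ 2) = σ(k₂ − x·β⁽²⁾)

where σ is the logistic function, so p₂ = P(d≤2) − P(d≤1) and a
positive coefficient raises the probability of worse levels. Covariates
marked *parallel* use a single packed parameter in both splits
(proportional odds); free covariates get an eq1/eq2 pair. The
all-parallel and no-parallel extremes are the ordered logit and the
fully generalized ordered logit.

Printed presentations of this model family sometimes show a
"1 − exp(·)" denominator; that form is not a probability, and the model
is implemented in the standard cumulative-logistic parameterization
above.

Estimation is maximum likelihood:

- Objective: mean negative log-likelihood with an analytic gradient.
  Any parameter point implying a non-positive category probability for
  an observed row returns an infinite objective (never an exception) so
  line searches back away from the invalid region.
- Starting values: cut points at the empirical cumulative logits with
  zero coefficients; partial specs start from the nested all-parallel
  fit (eq2 coefficients initialized equal to eq1).
- Optimizer: BFGS followed, if needed, by Newton polishing with a
  finite-difference Hessian of the analytic gradient. Convergence is a
  gradient max-norm below `gtol` on the mean-scaled objective (default
  1e−6; tests comparing against an external oracle request 1e−10).
  Non-convergence raises with diagnostics attached.
- Covariance: inverse observed information, the information being
  central finite differences of the analytic gradient at the optimum
  (step 1e−5·(1+|θ|)). A singular information matrix falls back to the
  pseudo-inverse and flags the fit.

**Negative middle probabilities.** Non-parallel cumulative curves can
cross, making the raw p₂ negative for some covariate patterns. This is
a known pathology of the model class, not an error: prediction flags
such rows, clamps p₂ to zero, renormalizes the row, and reports the
flagged fraction on the fit and in the pipeline log, because it is the
method's main silent failure mode. The *generator* (below) is held to a
stricter standard: truth configurations implying a negative p₂ anywhere
are rejected outright so simulation truth is always a clean oracle.

**Sparse extreme levels.** Survey data can have almost no level-3
responses on some dimensions (a fraction of a percent for mobility).
A response level absent from the data makes the three-level model
unidentified; the fit refuses, and an explicit `collapse_absent=True`
merges levels 2 and 3 into a binary logit (predictions then place zero
mass on level 3 — a documented optimistic bias for that dimension). A
response constant even after collapsing gets an add-one-smoothed
intercept-only fit flagged `degenerate`.

**Constraint selection.** `autofit` reproduces the gologit2-style
backward procedure: start unconstrained, repeatedly impose the
parallel-lines constraint on the free covariate with the largest Wald
p-value above α (default 0.05), refit warm-started, stop when all
remaining free covariates are significant. The Wald tests are
unadjusted for multiplicity, matching common practice; ties break on
design-column order, so the procedure is deterministic. An explicit
`PPOMSpec` overrides it entirely.

## Expected-utility conversion

Assuming independence of the five dimensions given the covariates (the
fitted model's structure), the probability of any state is the product
of its five level probabilities, and

    E[U] = Σ_{243 states} U(s)·Π_d p_{d,level_d(s)}
         = 1 − c·(1 − Π_d p_{d1}) − Σ_d (p_{d2}δ_{d2} + p_{d3}δ_{d3})
             − n3·(1 − Π_d (1 − p_{d3}))

The second (closed) form follows from the additivity of the tariff and
is the fast path; the enumeration is retained as the reference path and
the property suite asserts agreement to 1e−12 on random inputs.
Expected values — not sampled discrete profiles — are reported, so
mapped predictions are strictly inside the index whenever any row has
off-level-1 mass, and can never equal 1 for non-degenerate fits.

The default per-dimension design conditions on the other four
dimensions' *observed* responses (two indicators each, levels 2 and 3
versus none). This materially sharpens in-sample prediction but means
out-of-sample mapping requires the other responses to be present at
prediction time; pass `cross_dimension=False` to fit on external
covariates only.

## OLS comparator

Direct mapping regresses the utility index on the base covariates with
an intercept (numpy least squares; rank validation names collinear
columns, including collinearity with the intercept). Predictions are
deliberately not truncated: exceeding 1 on high-utility cohorts is part
of what the comparison measures. A `clamp` flag provides the post-hoc
repair for users who want it.

## Evaluation

MAE and RMSE overall and within sub-groups of the *actual* utility,
default bands (−∞, 0), [0, 0.5), [0.5, 0.75), [0.75, 1] —
lower-closed/upper-open except the top band. RMSE is the primary
squared-error metric; MSE is exposed as `rmse**2` for comparison with
studies reporting MSE. Distribution summaries report the histogram,
skewness and the share exactly at 1, the latter by float equality on
the scored index: only profile 11111 scores exactly 1.0, so the
expected-value predictions always report a zero share — by design.

## Synthetic cohorts

Individual-level EQ-5D survey data of the kind these models target is
restricted-access, so the generator produces cohorts with known ground
truth:

- **Covariates**: age from a truncated normal (default mean 58, sd 16,
  range 18–95; centred in decades as `age_c`, with `age_c2` derived,
  never sampled separately), sex, education (4 levels), acute sickness
  in the last two weeks (4), self-rated general health (5, reference
  "fair"), deprivation quartile, survey year (5 waves). Categorical
  level orders and reference categories are declared, never inferred.
- **Responses**: each dimension sampled from the cumulative-logistic
  model given the covariates. Truth is specified either with explicit
  cut points or with target cumulative marginals, in which case the cut
  points are calibrated by root-finding on the realized linear
  predictors, so marginal level shares match the targets by
  construction up to sampling noise.
- **True utility** is the tariff score of the realized profile.
- **Dependence**: responses are conditionally independent given the
  covariates by default (`latent_loading = 0`). A shared standard-
  normal severity factor can be loaded onto every dimension's linear
  predictor to induce the cross-dimension correlation real survey
  responses exhibit.

All randomness descends from one explicit seed through spawned
substreams, so covariate and response draws are independently
reproducible and reruns are byte-identical.

**Condition presets.** Six presets emulate the condition sub-groups of
a large English health survey (cardiovascular, diabetes, mental
health, musculoskeletal, nervous system, respiratory). Their marginal
level shares per dimension are the published sub-group profiles; the
shared covariate-effect template carries the signs observed in such
surveys (worse self-rated health, acute sickness, deprivation and age
increase problem probabilities; education decreases them), scaled per
dimension. The latent severity scale of each preset was calibrated once
(`scripts/calibrate_presets.py`) so the generated share at full health
matches the published sub-group share — under conditional independence
the product of the no-problem marginals (≈0.16 for the respiratory
profile) cannot reach the observed ≈0.42, so the latent factor is not
optional for realistic preset shapes. Calibrated scales: 2.15, 2.13,
1.02, 1.78, 1.68, 2.16 respectively.

What the presets do *not* emulate: the survey's sampling design and
weights, non-response, item missingness, the joint covariate
distribution of the real cohorts (covariate mixes are stipulated), or
any residual dependence structure beyond a single shared factor.
Passing benchmarks on these cohorts therefore demonstrates correctness
of the machinery and the qualitative behaviour of the two mapping
routes, not transportability of any particular coefficient to real
survey data.

## Benchmark pipeline

`run_benchmark` generates the six presets (default n = 10,000 each,
master seed 715), fits the OLS comparator on the base covariates and
one PPOM per dimension (base covariates plus the other dimensions'
response indicators; general-health dummies free, everything else
parallel, with automatic fallback to fully parallel if a partial fit
fails to converge), maps, and scores both prediction vectors against
the true utilities. On these cohorts the mapped predictions have
strictly smaller MAE and RMSE than OLS for every preset, stay inside
(−0.594, 1), and the OLS comparator predicts above 1 on the
high-utility (respiratory) cohort — the qualitative pattern the method
exists to demonstrate. Problem sizes in the test suite (50 recovery
replicates at n = 20,000; 200 Wald-calibration replicates at
n = 2,000; the six-preset benchmark at n = 10,000) were chosen to make
Monte Carlo error comfortably smaller than the tolerances asserted
while keeping a full run in the low minutes on one CPU.

## Known limitations

- Three response levels and the logit link only; no survey weights,
  clustering-robust variances, or Bayesian estimation.
- Cross-dimension conditioning limits out-of-sample use (above).
- The collapse escape hatch biases a collapsed dimension's level-3
  probability to zero.
- The mass at full health is not modelled separately (no two-part
  structure); expected-value predictions cannot reproduce it.
- Autofit's unadjusted sequential Wald tests inherit the usual caveats
  of stepwise selection.
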