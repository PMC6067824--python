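# Methods

## Model

`underdx` estimates the association between a binary exposure and a binary
outcome when the exposure is recorded with imperfect sensitivity and perfect
specificity. The concrete instance is 1-year hospital admission and a
schizophrenia diagnosis code in administrative claims. Writing *A* for
admission, *D* for the latent true diagnosis, *R* for the recorded code and
*X* for covariates:

- outcome: *A ~ Bernoulli(p)*, logit *p* = β₀ + β₁D + β′X;
- exposure: *D ~ Bernoulli(θ)* with θ the true 1-year period prevalence;
- reporting: *R | D ~ Bernoulli(s·D)*, so P(R=1|D=0) = 0 (no false-positive
  codes) and s = 1 − λ is the diagnostic sensitivity, λ the underdiagnosis
  rate.

The perfect-specificity assumption is substantive, not technical: clinicians
tend to delay a schizophrenia diagnosis rather than assign it loosely, so a
present code is trusted and only absence is questioned. Allowing false
positives would add a specificity parameter needing its own informative
prior; it is out of scope here.

The covariate vector is fixed at J = 9 terms besides the exposure: indicator
contrasts for the other hierarchically exclusive SMI groups (bipolar, PTSD,
MDD; reference = no SMI), age in decades (linear), female, Black and
other/missing race (reference = White), Hispanic ethnicity, and the Selim
physical-comorbidity count (0–30, linear). A latent D = 1 never alters the
recorded SMI indicators — the model corrects the exposure column only, the
covariates enter exactly as recorded.

## Priors and elicitation

- Coefficients β₁, β: Normal(0, 10 000); intercept β₀: Normal(−3, 10).
  **Variance parameterization throughout** (some BUGS-family tools use
  precision; the conversion is 1/variance).
- Prevalence θ: Beta(1, b) with b = (1 − m)/m solved so the mean is the
  scenario prevalence m. The Beta(1, ·) family is appropriate for rates known
  a priori to be small. Exact (real-valued) b is the default; a `round_shape`
  flag truncates b to an integer, reproducing conventionally printed shapes.
  Truncation (not nearest-integer rounding) is deliberate: it reproduces both
  587 (from 587.24) and 665 (from 665.67) for the moderate/high scenarios.
- Sensitivity s: Beta(m·n₀, (1−m)·n₀) with the scenario mean m and prior
  effective sample size n₀ = α + β fixed at 30 by default — the prior is
  "worth" 30 patient-level observations of diagnostic accuracy, mildly
  informative. n₀ is a free parameter.

Scenario means come from a prevalence chain: national 1-year prevalence
(default 0.5 %) × (1 − homeless fraction, default 20 %) = prevalence among
patients who can appear in the system; × adherence (default 50 %) =
observable prevalence (0.2 %); sensitivity = documented / observable
(0.13 % / 0.2 % = 65 %), gap = 0.07 %. The three built-in scenarios (low
0.20 %/65 %, moderate 0.17 %/76 %, high 0.15 %/87 %) differ in how much of
the documented shortfall is attributed to underdiagnosis.

## Sampler

Systematic-scan Metropolis-within-Gibbs with data augmentation, per
iteration:

1. **Latent truth.** For each unreported patient (R = 0), D is redrawn from
   its exact conditional
   θ(1−s)·L₁ / (θ(1−s)·L₁ + (1−θ)·L₀), where L_d is the Bernoulli likelihood
   of the observed outcome under D = d. Reported patients keep D = 1 by
   perfect specificity; this invariant is never violated by construction.
2. **Prevalence.** θ | D ~ Beta(α + ΣD, β + n − ΣD) (conjugate).
3. **Sensitivity.** s | D, R ~ Beta(α + #{R=1}, β + #{D=1, R=0}); only true
   cases carry information about s.
4. **Coefficients.** Coordinate-wise Gaussian random-walk Metropolis on the
   conditional log-posterior given D. Proposals are symmetric, so the accept
   ratio is the exact likelihood-times-prior ratio and detailed balance holds
   per coordinate. The likelihood difference for a proposal on coefficient j
   is accumulated only over rows where the j-th column is non-zero, with
   cached per-row log(1 + e^η) terms — for the sparse indicator columns this
   makes a sweep cost far less than 11 full-data likelihood evaluations.

**Adaptation.** Proposal scales start at 2.4/√(0.25·Σx² + 1/σ²_prior) (a
Fisher-information heuristic at p ≈ 0.5) and are multiplied by
exp(rate − 0.30) every 100 burn-in iterations, clipped to [10⁻⁵, 10³];
scales are frozen after burn-in, so the retained chain targets the exact
posterior. The upper clip is large enough that even a coefficient the data
barely constrain (prior sd 100) can reach the target acceptance band.

**Initialization.** Chain 0: D = R, θ and s at their prior means,
coefficients 0 except β₀ at its prior mean (−3). Odd chains are
overdispersed: coefficients shifted ±0.5 alternately, θ at its prior 90th and
s at its prior 10th percentile.

**Protocol.** Default 2 chains × (10 000 burn-in + 50 000 retained), thinning
1. Reproducibility: each chain's generator is seeded by (seed, chain index),
so a run is a pure function of the configuration. Memory stays bounded by
storing, besides the parameter draws, only the latent-case *count* among
unreported patients; an opt-in `store_latent` flag keeps the full latent
trace for small-cohort validation.

**Summaries.** Odds ratios are summarized as the posterior mean of
exp(draws) with equal-tailed percentile intervals (2.5/97.5 for 95 %),
chains pooled after burn-in. Equal-tailed intervals (not HPD) are the
reported convention. Convergence is monitored by the classic non-split
two-chain potential scale reduction factor √(((n−1)/n·W + B/n)/W); a split
variant is available by flag. The hard error threshold for R-hat input is
chain length ≥ 2; meaningful diagnosis of course needs far longer chains.

## Classical comparator

`naive.fit_logistic` is Newton/IRLS with step-halving (log-likelihood is
monotonically non-decreasing across iterations), convergence declared at
score max-norm < 10⁻⁸ within 100 iterations, Wald 95 % intervals
exp(β̂ ± z·SE). Perfect separation is detected (coefficient divergence past
|β| > 30 or a singular information matrix) and raised as an error naming the
offending column — never a silent result. Wald rather than profile intervals
is the deliberate convention for the comparator column.

## Synthetic cohorts

The generator emulates a 1-year adult claims cohort: the default parameters
reproduce the reference cohort's margins (N = 87 806; reported groups
schizophrenia 114 / bipolar 412 / PTSD 82 / MDD 5 793 / non-SMI 81 405;
57.4 % female; race 71.1/6.6/22.3 %; 5.4 % Hispanic; age mean 52.7, SD 18.9
on [18, 103]; Selim mean 1.7, SD 1.8). Defaults θ = 0.20 % and s = 65 % give
an expected documented prevalence of 0.13 %, i.e. ≈ 114 reported cases.

Design choices, where the real data's joint structure is unknown:

- Covariates are drawn **independently** at their margins — the minimal
  assumption; real claims data correlate age with comorbidity, so passing
  tests demonstrate correctness of the estimation machinery, not robustness
  to covariate dependence.
- Age is truncated-normal on [18, 103]; the parent location/scale are solved
  numerically so that the *truncated* moments equal the target mean/SD
  (truncating a Normal(52.7, 18.9²) directly would inflate the mean by
  ≈ 1.3 years).
- Selim is negative-binomial (moments matched to mean 1.7, SD 1.8) with the
  tiny tail above 30 redrawn.
- Generating outcome coefficients default to the reference study's fitted
  odds ratios with β₀ = −3. With these values the marginal admission
  probability is ≈ 10–11 %, somewhat above the reference cohort's 8.3 % —
  a consequence of anchoring β₀ and the odds ratios simultaneously; tests
  assert a qualitative single-digit-to-low-teens band rather than the exact
  reference percentage.
- Multiple SMI codes are resolved by the hierarchy schizophrenia > bipolar >
  PTSD > MDD, the order in which the groups are defined.

One documented inconsistency in the reference margins: the printed
per-group column headers swap the MDD and non-SMI totals (5 793 vs 81 405);
the generator follows the text-consistent sizes, under which the grouped
chi-square statistics reproduce exactly. The printed overall White-race
percentage (17.1) is likewise presumed a typo for 71.1 (62 394/87 806); the
generator uses the counts.

## Validation strategy and problem sizes

The original cohort is unavailable, so the reference results table is not
reproducible to the digit; validation is by properties instead, at sizes
chosen to keep the full suite in the tens of minutes on one core:

- exact reproduction of the grouped chi-square statistics (106.4, 728.2,
  50.4) from printed counts, and of the prior arithmetic;
- the 2×2 saturated logistic MLE equals the cross-product ratio; IRLS
  matches statsmodels on random designs;
- conjugate Gibbs draws match their closed-form beta posteriors (KS tests);
- on a 3-patient cohort with coefficients held at truth, latent marginals
  from the chain match exhaustive enumeration over the 2³ configurations
  with θ and s integrated analytically;
- with a sensitivity prior concentrated at 1 there is nothing to correct and
  the posterior mean of β₁ matches the naive MLE;
- parameter recovery: 20 replicate cohorts (n = 20 000, θ = 1 %, s = 0.7,
  β₁ = ln 2; single chains of 2 000 + 8 000), requiring ≥ 15/20 interval
  coverage of β₁ and mean posterior s within 0.1 of truth;
- two-chain R-hat for β₁ < 1.1 on a full-size (n = 87 806) default cohort at
  a reduced chain length (1 000 + 3 000).

## Known limitations

- Perfect specificity is assumed; no false-positive codes.
- Sensitivity is constant across patients — no covariate-dependent reporting
  and no exposure model with predictors.
- The generator does not model enrollment, attrition, repeat visits, or
  covariate dependence; homelessness and adherence enter only through the
  prevalence arithmetic.
- Coordinate-wise random-walk updates mix slowly relative to gradient-based
  samplers; the defaults compensate with chain length. Any exact alternative
  (e.g. Pólya-Gamma augmentation for the coefficient block) could be dropped
  in behind the same interface.
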