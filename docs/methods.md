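# Methods

## The scientific question

Clinical cardiovascular health (CVH), summarized as a 0–8 score over four
factors (BMI, blood pressure, total cholesterol, fasting glucose; 0 points
for a poor, 1 for an intermediate, 2 for an ideal category), declines with
age. The question this package operationalizes is *when* that decline
accelerates at the population level: are there specific ages — change points
— at which the mean rate of decline shifts, and do the rates between change
points differ by sex?

## Scoring model

Each examination is categorized factor-by-factor against the American Heart
Association clinical thresholds:

| factor | ideal | intermediate | poor |
|---|---|---|---|
| BMI (≥20 y), kg/m² | <25.0 | 25.0–29.99 | ≥30.0 |
| BMI (<20 y), percentile | <85th | 85th–95th | >95th |
| Blood pressure (≥18 y), mm Hg | <120/80 unmedicated | SBP 120–139 or DBP 80–89, or treated to <120/80 | SBP ≥140 or DBP ≥90 |
| Blood pressure (<18 y) | <90th pct (and <120/80, unmedicated) | 90th–95th pct, or SBP ≥120 or DBP ≥80 | >95th pct |
| Total cholesterol, mg/dL | <185 unmedicated | 185–219 or treated to <185 | ≥220 |
| Fasting glucose, mg/dL | <100 unmedicated | 100–125 or treated to <100 | ≥126 |

Boundary conventions are read literally from the printed intervals (25.0 and
29.99 are intermediate, 220 is poor, and so on). Two deliberate precedence
choices where the printed rules are silent: (i) in children, a reading below
the 90th percentile is still demoted from ideal when SBP ≥120 or DBP ≥80 or
the child is on antihypertensives — the absolute clause acts as a demotion
from ideal rather than only as an entry to intermediate; (ii) a missing
medication flag is treated as unmedicated. Pediatric percentiles (BMI below
age 20, BP below 18) are *inputs*, supplied through a pluggable provider;
computing them from CDC growth or pediatric-BP reference tables is out of
scope, and the synthetic generator emits them directly as the within-age/sex
normal rank of the simulated value (the BP percentile is the larger of the
systolic and diastolic ranks).

An exam contributes a score only if all four factors are categorizable at
that exam; subjects with no complete exam are excluded. This completeness
filter has a closed-form consequence under independent per-visit missingness
p with v visits: a subject is retained with probability 1 − p^v, which the
tests verify.

## Segmented linear mixed model

For subject *j* at age *t*, the score is modeled as

    y_ij = β0 + β1 (t_ij − 8) + Σ_k δ_k (t_ij − ψ_k)_+ + x_ij'η
           + b_0j + b_1j (t_ij − 8) + ε_ij,

with up to two change points ψ_1 < ψ_2, covariate dummies x (sex, race,
cohort; reference-coded with sorted level order), a bivariate-normal random
intercept and slope (unstructured 2×2 covariance G) and i.i.d. Gaussian
residuals. The mean is continuous and piecewise linear: the slope of segment
k is β1 + Σ_{j<k} δ_j (a telescoping identity the code maintains exactly).
Both fixed and random intercepts refer to age 8, the entry age of the
design, which also conditions the random-effect design matrix well.

Estimation is maximum likelihood throughout (not REML), because models with
different fixed effects are compared by LRT/AIC/BIC. The engine profiles the
fixed effects and the residual variance out of the marginal Gaussian
likelihood and optimizes only the three log-Cholesky parameters of G/σ²,
with an analytic gradient obtained by the envelope theorem. All per-subject
quantities reduce to 2×2 sufficient statistics computed once per design
matrix, so a refit after a knot moves costs a few batched matrix products —
this is what makes the iterative change-point search, the grid oracle and
the Monte-Carlo suites affordable. The test suite cross-checks the engine
against an independent ML implementation (statsmodels MixedLM with
reml=False): log-likelihoods agree to 1e−4 and coefficients to 1e−4 on a
seeded fixture.

### Change-point estimation

ψ is estimated by iterative linearization. At a working value ψ_k the break
term is expanded to first order, adding per change point the covariates
U_k = (t − ψ_k)_+ (coefficient δ_k, the slope increment) and
V_k = −1{t > ψ_k} (coefficient γ_k, the "gap"). The update is
ψ_k ← ψ_k + γ̂_k/δ̂_k, iterated until the largest movement is below
`tol_psi`. Numerical policies, all configurable:

* **Initialization** (`psi_init="grid"`, the default): a coarse
  profile-likelihood scan — locate the best single break on a 15-point grid,
  then scan the second break over the same grid conditional on the first.
  Every near-tied local maximum of the scan (within 2 log-likelihood units,
  up to three) seeds its own iteration and the best converged fit is kept.
  Plain quantile starts (`"auto"`: median, or 33rd/67th percentiles) are
  retained as an option but, when the second break is weak, they can leave
  the iteration in the basin of a spurious optimum with both breaks adjacent;
  a joint coarse lattice samples the sharp break too crudely and has the same
  defect. The hierarchical scan exploits the asymmetry that one break is
  typically strongly identified.
* **Local polish**: the profile likelihood in ψ is piecewise-smooth with
  kinks at observed ages and can carry shallow micro-bumps, so the fixed
  point of the linearization may stall slightly off the local maximum. After
  convergence a derivative-free refinement runs: a coordinate-wise sweep at
  0.25-year resolution within ±2 years (jumps local dips), then halving-step
  pattern descent to sub-0.05-year resolution, accepting improvements only.
  When competing optima tie to within ~1e−3 log-likelihood units — which
  happens at small n, where the break location is simply not identified at
  that resolution — the estimator returns one member of the tie; the
  delta-method CI, not the point location, carries the uncertainty.
* **Step control**: a proposed update is projected into the admissible range
  (observed ages shrunk by `min_gap`, default 3 years), re-ordered with the
  minimum gap enforced, and step-halved (up to 6 times) until the fixed-knot
  log-likelihood does not decrease; the accepted-iteration likelihood is
  therefore monotone. If no admissible improvement exists the current ψ is
  declared the optimum.
* **Degenerate kinks**: |δ̂_k| < 1e−10 makes the update undefined; the step
  is rejected and flagged (`DeltaZeroError`), and a fit ending in that state
  reports `converged=False`.
* **Convergence**: `tol_psi=1e−3` years, `max_iter=50` — three orders of
  magnitude below the 0.1-year reporting precision.
* **Inference**: reported coefficients, log-likelihood, AIC and BIC come
  from a final refit at ψ̂ without the V terms; AIC/BIC count the estimated
  change points as parameters in addition to the fixed effects and the four
  variance parameters. The SE of ψ̂ is the delta method on γ̂/δ̂ with the
  full (γ̂, δ̂) covariance from a working fit at ψ̂ — at convergence γ̂ ≈ 0
  and this reduces to SE(γ̂)/|δ̂|. CIs are ψ̂ ± 1.96·SE. Two change points
  are estimated jointly (both U/V pairs in one design) under a single ML
  criterion.

A brute-force **profile-likelihood grid oracle** (fit the fixed-knot model at
every admissible grid point, return the argmax and full profile) provides an
independent check; the acceptance suite requires the iterative estimate to
sit within one 0.5-year cell of the oracle argmax on seeded fixtures.

### Model selection and the interaction analysis

`compare_models` fits linear, quadratic and cubic mixed models and segmented
models with one and two change points by ML on identical data, ranks them by
AIC and BIC, and reports LRTs for nested pairs. Tests against a no-break
null are flagged as approximate: ψ is unidentified under the null (the
Davies problem), so AIC/BIC carry the default verdict.

The sex-difference analysis refits the mean as a piecewise-linear spline
with *fixed* knots (default 17 and 37 years, the rounded change-point
estimates) fully interacted with sex, adjusting for race and cohort, with
the random intercept+slope retained. Per-sex segment slopes and male−female
differences are linear contrasts with Wald inference. "Total change over a
segment" multiplies the **unrounded** slope by the window width (windows
default to 8–17, 17–37, 37–55.9 years); rounding is applied only in
presentation, since rounding first is not consistent with the printed
difference rows. Metric-level sex comparisons use Welch's unequal-variance
t-test on visits within ±0.5 years of each target age, with the convention
difference = male − female; two degenerate equal constant samples give p = 1.

## Synthetic cohort generator

The generator emulates a pooled multi-cohort longitudinal design: five
cohorts with overlapping baseline-age windows covering ages 8–55.99 years,
fixed per-cohort visit schedules (visits truncated at 55.99), baseline ages
uniform within each cohort's window, bivariate-normal random intercept
(defined at age 8) and slope, additive sex/race/cohort effects, and a
continuous piecewise-linear population mean. Scores are continuous by
default — the mixed model treats the 0–8 score as continuous, and a
continuous latent score keeps parameter recovery exact — with an option to
clamp to [0, 8] and round for realism experiments. Per-visit missingness
(`missing_exam_p`) marks an exam as lacking a factor; the completeness
filter then removes it.

The **paper2021** preset encodes the published adjusted-model estimates as
ground truth: ψ = (16.9, 37.2) years, segment slopes (0.01, −0.07, −0.08)
points/year. The five cohort blocks reproduce the pooled design's sampling
fractions (50/28/17/3/2 percent) scaled to 2,000 subjects, with baseline
windows (children 8–17/8–18, young adults 18–30) and 4–9 visits at 1–5-year
intervals so that observations cover the full 8–56-year range; sex and race
mixes give ~52% female and ~66% White. Variance components are **calibration
choices, not published values** (none are reported): re_sd_intercept = 1.0,
re_sd_slope = 0.012/year, correlation −0.25, residual SD 0.55 — a moderate
intraclass correlation with visit-level noise of about half a point, which a
sum of four categorized factors plausibly produces — chosen together with
the age-8 intercept (7.11) and small covariate effects so that the
first-exam score mean (SD) reproduces the published baseline 6.9 (1.2).
`missing_exam_p = 0.10` yields a realistic share of incomplete exams.
Two service presets support the validation suites: **single_break**
(ψ = 25, slopes 0 → −0.08, n = 300) and **linear_null** (no break, slope
−0.03).

Raw-metric mode emits the four clinical measurements instead of scores. Each
metric follows a sex-specific mean/SD trajectory anchored at ages 8, 17, 37
and 55 (piecewise-linear between anchors, flat outside), decomposed into a
stable subject-level offset (60% of variance) plus visit noise; percentile
columns are the within-age/sex normal rank of the value.

What the generator does **not** emulate: real cohort-specific measurement
protocols and secular trends, integer score granularity (by default),
informative missingness or dropout, within-visit correlation between the
four metrics, medication use (flags default to False), and behavioral
metrics (smoking, diet, physical activity). Passing recovery tests therefore
demonstrates correctness of the estimation machinery under the stated model,
not robustness to these real-data departures.

## What the validation suites compute

* **Recovery** (20 replicates, ~2,000 subjects each): replicate-mean ψ̂₁,
  ψ̂₂ and middle-segment slope, compared with the generating values at
  tolerances 0.5 y, 2 y and 0.01 points/y. The second break carries a small
  slope increment (−0.01), so single-replicate ψ̂₂ is genuinely diffuse
  (delta-method SEs of 2–7 years); the mean over replicates is the stable
  quantity. The information-criterion comparison against the 1-break model
  is exercised on the same replicates: AIC prefers the 2-break model
  essentially always, BIC in the clear majority — at this deliberately
  scaled-down n the BIC margin (2ΔlogLik vs 2·log n) is stochastic, and its
  decisiveness grows linearly with cohort size.
* **CI calibration**: 200 single-break cohorts at n = 300; the delta-method
  95% CI covers the generating ψ at 90–98% (observed ≈ 93%).
* **Oracle equivalence**: iterative estimate within one 0.5-year grid cell
  of the profile-likelihood argmax on seeded n = 150 fixtures.
* **Bias**: |mean ψ̂ − ψ| < 0.2 years under single_break at n = 1000
  (observed ≈ 0.13).

Problem sizes for all suites (20 replicates, 200 simulations, n = 150–2,000)
were chosen as the smallest designs at which the asymptotic claims under
test are expected to hold cleanly.

## Known limitations

* Random change points (subject-specific ψ) are not modeled; ψ is a
  population-level quantity.
* LRTs against a no-break null use a chi-square reference that is only
  approximate (Davies problem); they are flagged and AIC/BIC drive verdicts.
* The delta-method CI relies on asymptotic normality of γ̂/δ̂; with a very
  weak break (small |δ|) it can be badly calibrated, which is why the
  coverage suite uses the well-identified single-break design.
* Pediatric percentile computation is delegated; datasets lacking percentile
  columns simply mark those exams incomplete below the pediatric age cutoffs.
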