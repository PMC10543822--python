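# Methods

## The clock

PhenoAge is computed in three steps. The linear predictor is

    xb = b0 + Σ_i w_i · x_i + w_age · age,

where the nine biomarker terms enter untransformed except C-reactive
protein, which enters as ln(CRP). The coefficients are the published
Levine (2018) NHANES-derived values, shipped as a versioned JSON constants
file (`phenoage_levine_default`) rather than code, so an alternative
transcription can be substituted without touching the implementation; the
pipeline logs the SHA-256 of the constants file in use. The predictor maps
to a 10-year (120-month) mortality probability through a Gompertz
cumulative hazard with rate γ = 0.0076927 per month,

    M = 1 − exp(−exp(xb) · (e^(120γ) − 1)/γ),

and M maps onto the age scale with the inverse-Gompertz constants
a = −0.00553, b = 0.09165 per year, c = 141.50225 years:

    PhenoAge = c + ln(a · ln(1 − M)) / b.

**Units matter.** The weights assume albumin g/L, creatinine µmol/L,
glucose mmol/L, CRP mg/dL, lymphocyte % of WBC, MCV fL, RDW %, ALP U/L,
WBC 10⁹/L. Because silent unit mismatch is the dominant failure mode for
clock coefficients, the I/O layer carries an explicit per-analyte unit
table (CRP mg/L ÷ 10, glucose mg/dL ÷ 18.016, creatinine mg/dL × 88.42,
albumin g/dL × 10) and refuses unit codes it does not know.

**Degenerate inputs.** ln(0) is undefined, so CRP below 0.01 mg/dL is
clamped to that floor (configurable); labs report undetectable CRP as 0
routinely. The mortality risk is clamped into [1e−12, 1 − 1e−12] at both
ends so the age-scale inverse is always finite. For jointly extreme panels
the risk saturates to the upper clamp in double precision (any xb above
roughly −1.7 yields M = 1 to machine accuracy); inside the clamp region
PhenoAge is flat by construction. All validation errors name the offending
analyte.

## Recalibration

Three related measures are derived per patient: the signed age gap
(PhenoAge − age, in years); the residual of an ordinary least-squares
regression of PhenoAge on chronological age fitted over the whole cohort;
and the dichotomous acceleration flag, set when the residual is *strictly*
positive (a residual of exactly zero is not flagged). Plain OLS is used —
no robust or weighted variant — and recalibration is always within the
supplied cohort: the residual indexes a patient to the other patients
measured in the same context, which removes the clock's systematic upward
divergence with age and much of the context-wide shift that acute illness
imposes on everyone's bloods at once. The fitted intercept is reported as
the cohort's excess-PhenoAge threshold at which acceleration begins. The
signed (not absolute-value) gap is kept as the primary difference measure
because the direction of divergence is the quantity of interest; the
magnitude is derivable.

## Synthetic cohorts

The generator emulates a tertiary mixed medical–surgical ICU cohort: ages
truncated-normal (mean 62, SD 16, bounds 18–95 years, median ≈ 62);
eleven comorbidity flags Bernoulli at prevalences typical of such a unit
(e.g. chronic cardiovascular 7.7%, end-stage renal failure 4.3%,
cirrhosis 2.2%, diabetes 23.2%); elective surgery 27.4%. A latent
acceleration factor z ~ N(0, 1) is shifted upward per comorbidity
(strongest for end-stage renal failure, whose creatinine signature alone
guarantees a large clock shift), and drives both the biomarker means
(lab-realistic dispersions, CRP and ALP log-normal, values clipped into
assay ranges) and the death hazard. Survival uses an exponential death
time with per-day hazard

    h = h0 · exp(ln 2 · 1{z > 0} + 0.07 · (APACHE II − 15)),

log-normal discharge (median 10 days, log-SD 0.8) treated as censoring for
hospital death, and observed time = min(death, discharge). The baseline h0
is tuned by log-scale bisection until the expected mortality — conditional
on the drawn covariates and discharge times, mean(1 − exp(−h·D)) — equals
the 10% target; an unattainable target raises rather than silently
under-delivering. The acceleration effect enters through the *latent*
factor, not the computed residual, so the downstream PhenoAgeAccel flag is
a noisy measurement of truth; that is what makes attenuation and
parameter-recovery tests meaningful. Randomness is split into named child
streams (ages, comorbidities, latent, biomarkers, APACHE, discharge,
death, …) from one root `SeedSequence`, so adding a column never perturbs
earlier draws and cohorts are byte-identical given a seed.

What the generator does *not* emulate: admission-diagnosis mix, ICU
length-of-stay marginals, repeated measurements, informative missingness,
or measured biomarker summary statistics from any real cohort (lab
distributions use standard reference intervals shifted for critical
illness). Passing recovery tests therefore demonstrates correctness of the
estimators under the stated generative model, not validity on real ICU
data.

## Statistical battery

- **AUROC** is the Mann–Whitney concordance probability (ties ½), with
  variance and correlated-curve comparisons computed from DeLong placement
  values; CIs are normal-approximation, clipped to [0, 1]. Identical score
  vectors short-circuit to difference 0, p = 1 (the placement variance is
  exactly zero).
- **Cox models** maximise the Efron-tie partial likelihood via lifelines
  (Newton–Raphson precision 1e−9). Zero-variance covariates are reported
  as HR 1 with infinite standard error rather than crashing the fit. If
  Newton–Raphson halts on near-separation (a rare comorbidity with few
  events), the fit retries once with an L2 penalty of 0.01 and logs the
  retry; persistent failure raises with diagnostics. Harrell's C is
  computed on the fitted risk scores.
- **The sequential ladder** is forced sequential entry in a configured
  covariate order (demographics and chronic-health flags first, the
  APACHE II > 15 indicator last), reporting the focal hazard ratio at each
  nested step and the final model covariate-by-covariate. Forced order is
  the faithful reading of a table that adds one covariate per row
  regardless of significance; a p-threshold entry mode
  (`entry_p_threshold`) is available behind a flag. Severity is
  dichotomised at APACHE II > 15 in the final model, not entered
  continuously. Missing covariate values (diabetes documentation is
  incomplete in real cohorts) are handled complete-case per step, with the
  exclusion count recorded on every ladder row.
- **The spline curve** uses Harrell's restricted-cubic basis — one linear
  plus two truncated-cube terms normalised by the squared boundary-knot
  span, linear beyond the boundary knots — with 4 knots at the
  5/35/65/95 percentiles of the residual distribution (standard placement).
  The log-HR curve is referenced to residual 0 (exactly zero there by
  construction) with delta-method 95% bands; nonlinearity is the joint
  Wald test of the two nonlinear coefficients.
- **Descriptive tables** use Pearson chi-square without continuity
  correction for categorical variables and two-sided Mann–Whitney with
  median (IQR) for continuous ones; variables constant in both groups are
  flagged and skipped. All tests are two-sided at α = 0.05.
- **Comorbidity odds ratios** are 2×2 with Woolf logit 95% CIs; any zero
  cell triggers the Haldane–Anscombe 0.5 correction, flagged in the
  output.
- **Sample size** follows Hanley–McNeil (1982): Q1 = θ/(2−θ),
  Q2 = 2θ²/(1+θ), with the null variance at θ0 = 0.5, returning the
  smallest positive count (negatives at a fixed ratio, default 10:1
  matching ≈9% mortality) satisfying
  z_{1−α/2}·√V0 + z_{power}·√V1 ≤ θ − 0.5. Defaults α = 0.05 two-sided,
  power 0.80.
- **Survival curves**: Kaplan–Meier with log-rank for the unadjusted
  comparison; the adjusted curves use the mean-covariate method (predicted
  survival at cohort-mean adjusters with the flag set to 0/1), a
  deliberate choice among the adjustment methods available.

## Filters

Panel selection from long-format labs keeps draws with sample time in
[0, 24] hours from ICU admission (pre-admission draws excluded), takes the
earliest draw per analyte, and includes a patient only when all nine
analytes are present; every excluded patient carries exactly one recorded
reason. The readmission filter keeps the first ICU admission per
hospitalization and rejects duplicate (hospitalization, order) pairs.

## Problem sizes and tolerances in the test suite

Simulation-recovery checks use 200 cohorts of n = 3000 for hazard-ratio
recovery (mean HR within [1.9, 2.1] of the true 2.0, CI coverage within
[0.92, 0.98]); 100 seeds of n = 1200 for the spline type-I check
(≤ 10% rejections at α = 0.05); 30 seeds of n = 4000 for plateau recovery
(sign test, ≥ 24/30); and a single n = 50 000 cohort for mortality
calibration (±1 absolute point). Oracle-equivalence checks run at 1e−9
(clock, vs direct formula evaluation), 1e−12 (AUC vs exhaustive pair
counting), and 1e−6 (the three-observation Cox fixture vs its closed
form). These sizes give comfortable statistical margins for the stated
bands while keeping the default run fast.

## Known limitations

- The exponential death-time model has no time-varying hazards or
  competing-risks structure; discharge is censoring, as in the hospital-
  mortality Cox framing, and no Fine–Gray analysis is offered.
- The near-separation ridge fallback slightly shrinks coefficients in the
  rare small-cohort fits that trigger it; it is logged whenever used.
- Duplicating every observation is an exact invariance of the Cox partial
  likelihood only under Breslow tie handling; the Efron fit shifts
  slightly because duplication creates ties that Efron downweights.
- The entry-p stepwise mode is a simple single-pass forward screen, not a
  full add-drop stepwise search.
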