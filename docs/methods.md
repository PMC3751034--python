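# Methods

`lifedose` reconstructs lifetime doses of a traffic-emitted pollutant
(benzo(a)pyrene as the PAH proxy) for subjects of a case-control study, in
the presence of three kinds of gaps: calendar years before usable
emission/traffic records exist, years a subject lived outside the study
area, and residences whose address could not be geocoded. This note
documents the models, the parameters that matter, the numerical choices,
and what the synthetic experiments do and do not establish.

## Risk model and effective dose

Disease risk follows a logistic model linear in accumulated dose,

    ln p/(1-p) = A + beta * (Z_calc + Z_imp),

where `Z_calc` is the dose accumulated over periods with complete
individual information and `Z_imp` the imputed remainder. The dose is an
*effective* dose: yearly exposures E(y, i) are weighted by a biological
effectiveness factor B before summation, so that equal Z means an equal
log-odds increment regardless of exposure timing. Four forms of B span
the plausible age sensitivities:

| form | meaning | implementation |
|------|---------|----------------|
| B1 | constant | plain cumulative sum |
| B2 | inverse-square of onset age | `(reference_age / onset_age)^2`, constant across exposure ages |
| B3 | threshold / peak | dose = maximum annual exposure; optional `Z > theta` indicator in the regression |
| B4 | pure promoter | only the last k years before the stop year count |

A latency L shifts the summation stop year back by L. B2's square law is
normalised at a configurable reference age (default: cohort mean onset
age); the normalisation is a pure rescaling of Z and does not affect
correlations or regression z-statistics. Under B3 the peak year's
provenance decides whether the whole dose is modeled or imputed, since
the peak is a single year.

Yearly exposure factorises as E = eps(y) * T(y) * D(y, r), with eps the
per-vehicle emission factor, T the average vehicles per km, and D the
residence transfer function. The emission factor is held constant before
the record boundary year at its boundary value.

## Dispersion model

D is computed from a planar road network by treating each straight
segment as a finite line source and integrating a ground-level,
sector-averaged Gaussian kernel along it. Because the meteorology is a
monthly climatology (a wind rose over >= 8 sectors with per-sector speeds
and Pasquill-style stability classes with power-law spreads
sigma = a x^b), wind direction is uniform within a sector, and the
crosswind Gaussian averages to a uniform spread over the sector arc:

    chi(r) = 2 p_k / (sqrt(2 pi) * u_k * sigma_z(r) * W(r)),
    W(r) = max(r * dtheta, sqrt(2 pi) * sigma_y(r)),

with ground reflection included and sigma_z capped at 0.8x the mixing
height. The sigma_y floor on the lateral width W only binds for very
fine roses. Receptors within 1 m of a source are clamped to 1 m and
flagged.

Numerics: the line integral uses a composite midpoint rule — 128 nodes
inside 100 m of the road, 24 nodes beyond 120 m, and a linear cross-fade
of the two between 80 and 120 m so the field is continuous everywhere.
Against a 1000-sub-point reference quadrature the error is below 0.1% at
all tested distances (20 m to 2 km), well inside the 5% tolerance used in
the tests. Segments inside intersection zones carry an emission boost
(idling/acceleration emissions exceed cruise emissions); street-canyon
effects, plume depletion and terrain are not modelled.

Normalisation: the received exposure per unit emission factor is divided
by T(y), so that D measures concentration per unit average-vehicle
emission and E = eps * T * D recovers the concentration. An additive
background (pollution advected into the area) is applied once per
receptor, outside the division, which preserves both the
traffic-rescaling invariance and sub-network additivity of D.

## Group-level surrogates

**Early surrogate** (years before the record boundary): regional vehicle
registrations scale the boundary-year mean individualised dose,
`V1(i) * (Vehicles(t)/Vehicles(boundary))^k1 * mean_dose`. **Out-of-area
surrogate** (in-record years outside the area):
`k2 * V2(i) * eps(t) * T(t) * <D(t)>` with `<D(t)>` the cohort-average
transfer value of in-area subjects that year. `k1` and `k2` (default 1)
are sensitivity knobs, not fitted coefficients.

Both surrogates are individualised by mean-one lognormal variates
(`V = exp(sigma*xi - sigma^2/2)`; the analytic mean is exactly 1 for any
sigma) whose variance is matched to the spread of individualised doses:
`sigma^2 = ln(1 + CV^2)` from the boundary-year doses for V1, and per
five-year window for V2. The lognormal family is chosen because doses
are non-negative and right-skewed; the matching targets only mean and
variance. Calibration is done **separately for cases and controls**;
this arm separation is what carries the observed case-control dose
contrast into the surrogate and keeps pooled regression coefficients
from attenuating toward the null. V1 is drawn once per subject per
imputed dataset, V2 once per subject per window per imputed dataset.

Because the scaler means are themselves estimated from finite samples,
each imputed dataset redraws them from their sampling distribution
(normal, subject-level SE). This propagates the group-calibration
uncertainty into Rubin's between-imputation variance; without it,
replicate-level coverage of the pooled CI fell by roughly ten points.

Accrual of the early surrogate starts at birth by default
(`surrogate_start_age` is configurable). The analysis pipeline excludes
the early surrogate from the default dose variable: including it gives
nearly every subject a nonzero imputed component, emptying the
complete-case stratum that the PDI diagnostics are built around. It can
be switched on (`include_early_surrogate=True`) when lifetime rather
than record-period dose is wanted.

## Imputation of missing transfer values

Two methods, intended to be compared:

* **Interpolation** — log-linear in time between the subject's nearest
  residences with known D, multiplied by mean-one lognormal noise with
  sigma = |ln D_prev - ln D_next| / 2 (the two-point fit). At a history
  end the single neighbour is carried with sigma = 0, so those values are
  identical across imputed datasets. Log-scale interpolation respects
  positivity and the lognormal noise model; mean-one noise keeps the
  natural-scale mean unbiased. The method uses no covariates and no
  outcome, which makes it simple but mildly attenuating.
* **Place** — hot-deck predictive-mean matching restricted to donors in
  the same small geographic area ("place", roughly 1% of the region): a
  linear predictor of ln D on the covariates *including case-control
  status* is fit over the place's donors, and the imputed value is drawn
  uniformly from the five donors with nearest predictions. Pools with
  fewer than five donors in either arm fall back to interpolation; when
  that is also impossible the value is drawn from the whole-cohort
  donor pool with a logged warning. Because only observed values are
  re-used, the method reproduces non-standard (heavy-tailed) D
  distributions that no parametric family fits.

Missing covariates are completed first by five cycles of fully
conditional specification (continuous: PMM with q = 5; categorical:
within-arm frequency draws). M = 15 completed datasets are generated by
default, each from an independent `SeedSequence` substream, so results
are bit-reproducible under (seed, M, method).

## Incompleteness diagnostics

PDI = 100 * Z_imp / (Z_imp + Z_calc) is the percentage of dose imputed;
PTI the percentage of covered years imputed (less conservative when
exposure varies strongly over time). A subject with both components zero
is flagged degenerate and assigned PDI 100. Case/control counts by PDI
stratum ({0}, (0,20), [20,40), [40,60), [60,80), [80,100]) are tested
for independence with a plain Pearson chi-square (no continuity
correction; the expected counts in a 6x2 table at cohort sizes are
large). An association between PDI and case status signals possible
recall bias — interview-based residence histories may be recalled
differently by cases and controls — and the prescribed response is to
repeat the regression under PDI caps (0 = complete-case, ...,
100 = everyone) and check consistency.

Tail diagnostics order the log doses against normal quantiles (Blom
plotting positions) with a pointwise 95% order-statistic band obtained
from the beta distribution of uniform order statistics, mapped through a
robustly fitted normal (median and normalised IQR, so a heavy upper tail
cannot inflate the fitted scale and mask itself).

## Pooling

Per-imputation logistic fits (Newton-Raphson, tolerance 1e-8, observed
information variances; age always among the covariates because the
surrogates are strongly age-correlated) are combined with Rubin's rules:
q̄ = mean(q_m), W = mean(u_m), B = var(q_m),
T = W + (1 + 1/M) B, df = (M-1)(1 + W/((1+1/M)B))^2, with B = 0 treated
as infinite df. The Barnard-Rubin small-sample df is available behind
the classical default. PDI-capped subsets are formed per imputation,
since a subject's PDI depends on the imputed values.

## Synthetic cohorts

The generator emulates the structure such a study presents, at desk
scale (defaults: 2,000 subjects, a 20x20 km region with ~2,000 road
segments, 400 candidate home sites):

* a grid of minor roads (street volumes lognormal across streets) plus
  sparse major roads, modulated by a smooth random log-density surface
  (the urbanisation gradient), which makes site transfer values
  approximately lognormal;
* intersection zones where major roads cross, with boosted emissions,
  and housing hard against the busiest crossings — occupied long-term by
  the configured 1% "intersection tail" of subjects (low-income by
  construction, which is what lets covariate-conditioned imputation see
  the tail);
* in-migration: ~55% of subjects arrive after the 1960 record boundary;
* interview-style missingness: geocoding success follows a logistic
  curve in calendar year anchored at 65% success in 1960; failed
  geocodes retain the place label 80% of the time; under MAR the
  masking probability also shifts with education, never with D or case
  status;
* outcomes drawn from the logistic risk equation with a known
  coefficient (log odds ratio 1.5 per SD of true dose by default); the
  intercept is solved by bisection for the target case fraction, and an
  age-stratum offset emulates frequency matching of controls to the
  case age distribution.

Ground truth (true D histories, true doses, case probabilities) lives in
a `TrueState` container that estimation code never imports — a test
audits the module sources for this.

Out-of-area truth is drawn from the *ordinary-housing* D distribution:
the intersection tail is a feature of the study area, and out-of-area
truth drawn from it would be irrecoverable noise for any imputation.

**Study sizes in the experiments.** The test suite's recovery experiment
runs 100 replicates of n = 2,000 cohorts on a ~260-segment network with
250 sites, M = 15, ~40% MAR missingness and 10% in-migration; the
distributional and tail experiments use single cohorts of 1,000–2,000
subjects on a ~1,100-segment network. These sizes give stable statistics
while keeping the full suite fast; all of them are configuration, not
code.

## What the synthetic experiments show — and what they do not

Passing tests establish that the machinery is self-consistent: surrogate
means and variances match at the record boundary, completed doses remove
the artefactual dependence of dose on arrival year, place imputation
preserves the overall D distribution (MCAR, two-sample KS) and the
99th-percentile tail within 25%, the complete-case stratum is exactly
the PDI = 0 subset, and pooled 95% CIs cover the true coefficient in
>= 90% of replicates under ~40% residence-level MAR missingness with
modest in-migration.

Two caveats delimit what this says about real data. First, with heavy
in-migration (55% arriving after the boundary), roughly half of a late
arriver's dose is a group-level surrogate whose subject-level truth is
unknowable; pooled CIs then under-cover the true-dose coefficient no
matter the pooling rule, and with a skewed dose distribution the
arm-anchored surrogate can amplify the case-control contrast. This is
precisely why the PDI-capped analysis sequence exists: consistency of
estimates across caps, not the full-population fit alone, is the
evidence. Second, the generator's missingness is driven by year and
covariates only; differential recall by case status is deliberately
absent. The PDI-by-case-status chi-square can nevertheless reject on
some synthetic cohorts: the covariates that drive missingness
(education) also correlate with exposure and hence with case status, so
a PDI-case association is a *flag*, not proof, of differential recall —
the capped regression sequence, not the chi-square alone, carries the
inference.

## Known limitations

* The near/far dispersion switch uses a documented 80–120 m linear
  cross-fade; the kernel is a climatological sector average, not an
  hour-by-hour puff tracker, and omits street canyons, deposition and
  terrain.
* B2 is a pure function of onset age, matching the operational
  "cumulative dose x (onset age)^-2" variant rather than a per-exposure
  age weighting.
* Pearson chi-square on the 6x2 PDI strata is the only independence
  test offered; small-expected-count corrections are out of scope.
* k2 is a sensitivity multiplier only; treating it as a fitted
  regression coefficient is out of scope.
* Interpolation imputation can overstate imputed values under a long
  exposure tail, and place imputation can understate low values when
  tail values cluster geographically — the reason both are provided and
  should be compared.
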