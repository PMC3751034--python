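# lifedose

Lifetime traffic air-pollution dose reconstruction for case-control
studies, with multiple imputation of historical gaps and recall-bias
diagnostics.

Environmental epidemiology over the life course needs exposure estimates
for decades in which the record is incomplete: emission and traffic data
may not exist before some boundary year, subjects migrate into the study
area mid-life, and interview-recalled addresses often cannot be geocoded.
`lifedose` implements a reconstruction framework for this setting,
exercised end-to-end on synthetic cohorts. It is written for
epidemiologists and exposure modellers who want to test such a pipeline —
dose model, surrogates, imputation, pooling and diagnostics — under known
ground truth.

## The model

Disease risk is logistic in accumulated ("effective") dose,

```
ln p_i/(1 - p_i) = A + beta * (Z_calc(i) + Z_imp(i)),
Z(i) = sum_{y'=y_b}^{y_stop} E(y', i) * B(y' - y_b, y - y_b),
E(y', i) = eps(y') * T(y') * D(y', r_i[y']),
```

where `eps` is the per-vehicle emission factor (benzo(a)pyrene as the PAH
proxy), `T` the average vehicles per km, `D` the dispersion transfer
function of the residence `r_i`, and `B` a biological-effectiveness
weight (constant, inverse-square onset age, peak-only, or promoter
forms). `Z_calc` accumulates over years with complete individual
information, `Z_imp` over imputed years. The gaps are filled by:

* an **early surrogate** for pre-record years, scaling the boundary-year
  mean dose by vehicle-registration ratios;
* an **out-of-area surrogate** replacing `D` with the cohort average
  `<D(t)>` for years lived outside the area;
* **multiple imputation** of missing residence transfer values, by
  log-linear interpolation with lognormal noise or by place-restricted
  hot-deck predictive-mean matching conditioned on covariates including
  case status.

Surrogates are individualised by mean-one lognormal variates with
variance matched to the individualised doses, separately for cases and
controls. M completed datasets (default 15) are analysed by logistic
regression and combined with Rubin's rules. The **PDI** incompleteness
index, `100 * Z_imp / (Z_imp + Z_calc)`, stratifies every analysis:
PDI = 0 is the complete-case analysis, and consistency of estimates as
the PDI cap grows is the guard against imputation artefacts and recall
bias. See `docs/methods.md` for the full account.

## Worked example

Generate a synthetic cohort with known dose effect, mask it the way an
interview study would, and run the pipeline:

```python
import warnings; warnings.filterwarnings("ignore")
import numpy as np
from lifedose import pipeline
from lifedose.diagnostics import chi_square_independence, pdi_strata_table
from lifedose.synthetic import (CohortConfig, apply_missingness,
                                default_emission_series,
                                default_traffic_series, generate_cohort)

cfg = CohortConfig(n_subjects=600, n_sites=150, minor_spacing_km=2.0,
                   n_major_roads=4)
cohort, truth = generate_cohort(cfg, seed=11)
observed = apply_missingness(cohort, seed=11)

result = pipeline.run(observed, default_emission_series(),
                      default_traffic_series(), None,
                      pipeline.PipelineConfig(m_imputations=15,
                                              imputation_method="place"),
                      seed=11)

pooled = result.pooled
dose_rows = pooled[pooled["term"] == "z_total"]
print(dose_rows[["pdi_cap", "n_mean", "estimate", "ci_low",
                 "ci_high"]].to_string(index=False))

pdi = result.pdi[0]
table = pdi_strata_table(
    pdi["pdi"].to_numpy(),
    observed.subjects.set_index("subject_id")
    .loc[pdi["subject_id"], "case"].to_numpy())
stat, df, p = chi_square_independence(table[["controls",
                                             "cases"]].to_numpy())
print(f"PDI x case-status chi-square: {stat:.2f} (df={df}), p = {p:.3f}")
print(f"true dose coefficient: {truth.beta:.1f}")
```

Output:

```
 pdi_cap     n_mean  estimate     ci_low   ci_high
     0.0  88.000000  0.174676 -24.813451 25.162803
    20.0 197.600000  8.035580 -13.573522 29.644683
    40.0 271.866667  8.068529 -13.517228 29.654286
    60.0 324.600000  8.529076 -13.279213 30.337366
    80.0 392.466667  8.375350 -13.549535 30.300236
   100.0 600.000000  8.509277 -16.751014 33.769568
PDI x case-status chi-square: 1.95 (df=5), p = 0.856
true dose coefficient: 33.6
```

Reading it: each row is the Rubin-pooled dose coefficient for subjects
whose percentage of imputed dose is at most `pdi_cap`; `n_mean` is the
average subset size across the 15 imputations. The estimates are stable
from cap 20 upward — the consistency-across-caps pattern that justifies
extending a complete-case analysis to the full cohort. The chi-square on
the PDI strata is null here (p = 0.86); the generator builds in no
differential recall by case status, though on other seeds a benign
PDI-case association can appear because the covariates driving
missingness also correlate with exposure — one more reason the capped
regression sequence, not the chi-square alone, carries the inference. The confidence intervals are wide and
the point estimates sit below the true coefficient because this cohort
has heavy in-migration (~55% arrive after the record boundary), so much
of the dose is group-level surrogate; at this size only the sign and the
cap-consistency are informative, which is exactly the method's point.

A command-line interface wraps the same stages:

```
lifedose simulate --seed 5 --out simdir
lifedose run --cohort-dir simdir --seed 5 --out outdir -m 15 --method place
```

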