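# phenoaccel

Biological-age scoring and age-acceleration mortality analysis for ICU
cohorts.

Clinicians have long suspected that *biological* age — how worn a body
actually is — predicts outcomes of critical illness better than the age on
the chart. `phenoaccel` implements the full analysis pipeline for testing
that idea on a cohort of intensive-care patients:

1. **PhenoAge scoring** — the Levine phenotypic-age clock, which maps
   chronological age plus nine routine blood tests (albumin, creatinine,
   glucose, CRP, lymphocyte %, MCV, RDW, alkaline phosphatase, WBC)
   through a weighted linear predictor `xb`, a Gompertz 10-year mortality
   risk

       M = 1 − exp(−exp(xb) · (e^(120γ) − 1)/γ),

   and an inverse transform back to an age scale:

       PhenoAge = c + ln(a · ln(1 − M)) / b,   a < 0.

2. **Within-cohort recalibration** — OLS of PhenoAge on chronological age
   over the whole cohort; the residual indexes each patient to their peers
   in the same context, and **PhenoAgeAccel** flags patients whose residual
   is strictly positive (biologically older than expected).

3. **Outcome analysis** — AUROC discrimination with DeLong comparisons, a
   sequential Cox proportional-hazards adjustment ladder (Efron ties)
   ending in a full model with an APACHE II > 15 severity indicator,
   a 4-knot restricted cubic spline log-hazard curve for the residual,
   descriptive chi-square / Mann–Whitney tables, comorbidity odds ratios
   for the acceleration flag, Kaplan–Meier and mean-covariate adjusted
   survival curves, and the Hanley–McNeil AUROC sample-size calculation.

4. **Synthetic ICU cohorts** — a generator with a known latent
   acceleration factor that doubles the death hazard, discharge treated as
   censoring, and a bisection-tuned baseline hazard hitting a target
   hospital mortality, so every stage is testable with ground truth and no
   patient data.

The package is aimed at intensive-care outcomes researchers and
biostatisticians who want a tested, reproducible implementation of the
clock and its downstream mortality analysis.

## Worked example

```python
from phenoaccel import BiomarkerPanel, compute_phenoage, validate_panel

panel = validate_panel(BiomarkerPanel(
    albumin=40.0, creatinine=80.0, glucose=5.0, crp=0.1,
    lymphocyte_pct=30.0, mcv=90.0, rdw=13.0, alp=70.0, wbc=7.0,
))
r = compute_phenoage(panel, age=60.0)
print(f"{r.xb:.4f} {r.mortality_risk:.4f} {r.phenoage:.2f}")
```

prints

```
-8.0410 0.0615 54.71
```

— a 60-year-old with this unremarkable panel has a 6.2% modelled 10-year
mortality risk, equivalent to a phenotypic age of 54.7 years: biologically
a little *younger* than the calendar age.

Running the whole pipeline on a simulated cohort
(`python examples/04_mortality_analysis.py`) prints, among other sections:

```
AUROC for hospital mortality
  age_years              0.539 (0.504-0.573)
  phenoage_years         0.599 (0.566-0.632)
  accel_residual_years   0.606 (0.573-0.638)

Sequential Cox ladder (focal hazard ratio for the acceleration flag)
   1 terms: HR 1.801 (1.427-2.272)
   ...
  15 terms: HR 1.460 (1.130-1.886)
```

The acceleration flag roughly halves its excess hazard once comorbidities
and illness severity enter the model, but remains independently
prognostic — exactly the attenuation structure the analysis is designed to
quantify. The other `examples/*.py` scripts each demonstrate one
capability (scoring, recalibration, simulation, panel selection from raw
labs, power calculation).

A thin CLI wraps the same functions:

```bash
phenoaccel simulate --n 2950 --seed 7 --out cohort.csv
phenoaccel score   --cohort cohort.csv --out scored.csv
phenoaccel accel   --cohort scored.csv --out accel.csv
phenoaccel analyze --cohort accel.csv  --out report/
phenoaccel power   --auc 0.6
```

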