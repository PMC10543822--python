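"""The full mortality analysis on a simulated cohort.

Runs the end-to-end pipeline (filters -> scoring -> recalibration ->
statistical battery) and prints the discrimination comparison and the
sequential Cox adjustment ladder.
"""

from phenoaccel import PipelineConfig, SimulationConfig, run_pipeline

cohort, report = run_pipeline(PipelineConfig(
    simulation=SimulationConfig(n=2950, seed=7),
    with_adjusted_curves=False,
))

print("AUROC for hospital mortality")
for name in ("age_years", "phenoage_years", "accel_residual_years"):
    r = report.roc[name]
    print(f"  {name:22s} {r['auc']:.3f} ({r['ci_low']:.3f}-{r['ci_high']:.3f})")
cmp = next(c for c in report.roc_comparisons if c["scores"][0] == "phenoage_years")
print(f"  DeLong PhenoAge vs age: diff {cmp['difference']:+.3f}, p = {cmp['p_value']:.2g}")

print("\nSequential Cox ladder (focal hazard ratio for the acceleration flag)")
for row in report.ladder.rows:
    print(f"  {len(row.model_terms):2d} terms: HR {row.focal_hr:.3f} "
          f"({row.ci_low:.3f}-{row.ci_high:.3f})")
print(f"\nHarrell's C of the final full model: {report.ladder.final_model.concordance:.3f}")
print()
print("The univariable hazard ratio attenuates as comorbidities and the"
      " APACHE II > 15 severity indicator enter, but the acceleration flag"
      " keeps independent prognostic value - the residual confounding left"
      " after adjustment is what the ladder quantifies.")
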