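"""Generate a synthetic ICU cohort with known ground truth.

The latent acceleration factor z doubles the death hazard when positive;
the baseline hazard is tuned by bisection so expected hospital mortality
hits the configured target.
"""

import numpy as np

from phenoaccel import SimulationConfig, generate_cohort, true_parameters

config = SimulationConfig(n=2950, seed=7)
cohort = generate_cohort(config)
truth = true_parameters(config)

print(f"patients            : {len(cohort)}")
print(f"median age          : {cohort['age_years'].median():.0f} years")
print(f"hospital mortality  : {100 * cohort['died_in_hospital'].mean():.1f}%")
print(f"true accel HR       : {np.exp(truth.accel_log_hr):.3f}")
print(f"tuned baseline      : {truth.baseline_hazard:.5f} per day")
print(f"expected mortality  : {truth.expected_mortality:.3f} "
      f"(target {truth.target_mortality})")
print()
print("Comorbid patients carry an upward-shifted latent factor, so"
      " accelerated aging is enriched in chronic disease; the factor drives"
      " both the blood panel and the hazard, which is what downstream"
      " recovery tests exploit.")
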