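"""Synthetic ICU cohort generator with known ground truth.

Emulates a mixed medical–surgical ICU cohort: ~3000 patients, median age in
the low 60s, ~10% hospital mortality, comorbidity prevalences typical of a
tertiary ICU. A latent age-acceleration factor ``z`` (standard normal,
shifted upward by comorbidity-specific increments) drives both the blood
biomarkers and the death hazard, so the PhenoAgeAccel flag computed
downstream is a *noisy measurement* of the ground truth ``z > 0`` — which
is what makes attenuation and parameter-recovery tests meaningful.

Survival model: death time is exponential with per-day hazard

    h_i = h0 * exp(accel_log_hr * 1{z_i > 0} + apache_log_hr * (apache_i - 15)),

discharge time is log-normal (median ``discharge_median_days``), and the
observed outcome is whichever comes first; discharge censors hospital
death. The baseline ``h0`` is tuned by bisection so the expected mortality,
conditional on the drawn covariates and discharge times, equals
``target_mortality``.

Randomness is split into named child streams from one root seed, so adding
a column never perturbs earlier draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = ["SimulationConfig", "TrueParameters", "generate_cohort", "true_parameters", "COMORBIDITIES"]

#: Comorbidity flags carried by the cohort table, in column order.
COMORBIDITIES = (
    "chronic_respiratory",
    "chronic_cardiovascular",
    "end_stage_renal_failure",
    "cirrhosis",
    "immune_disease",
    "immunosuppressed",
    "lymphoma",
    "leukemia",
    "metastatic_cancer",
    "aids",
    "diabetes",
)

#: Default prevalence per comorbidity (whole-cohort fractions typical of a
#: tertiary mixed ICU).
DEFAULT_PREVALENCES = {
    "chronic_respiratory": 0.041,
    "chronic_cardiovascular": 0.077,
    "end_stage_renal_failure": 0.043,
    "cirrhosis": 0.022,
    "immune_disease": 0.022,
    "immunosuppressed": 0.080,
    "lymphoma": 0.019,
    "leukemia": 0.018,
    "metastatic_cancer": 0.055,
    "aids": 0.002,
    "diabetes": 0.232,
}

#: Upward shift on the latent acceleration factor per comorbidity: chronic
#: disease enriches accelerated aging, strongest for end-stage renal
#: failure (its creatinine signature alone guarantees a large clock shift).
DEFAULT_Z_SHIFTS = {
    "chronic_respiratory": 0.2,
    "chronic_cardiovascular": 0.4,
    "end_stage_renal_failure": 1.5,
    "cirrhosis": 0.6,
    "immune_disease": 0.3,
    "immunosuppressed": 0.3,
    "lymphoma": 0.2,
    "leukemia": 0.2,
    "metastatic_cancer": 0.1,
    "aids": 0.3,
    "diabetes": 0.6,
}

#: Additive mean shifts on individual biomarkers per comorbidity, on top of
#: the latent-factor effect (canonical units).
DEFAULT_BIOMARKER_SHIFTS: dict[str, dict[str, float]] = {
    "end_stage_renal_failure": {"creatinine": 350.0},
    "diabetes": {"glucose": 3.0},
    "cirrhosis": {"albumin": -6.0, "alp": 60.0},
    "leukemia": {"wbc": 15.0},
    "lymphoma": {"lymphocyte_pct": 8.0},
}


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one synthetic cohort."""

    n: int = 2950
    seed: int = 0
    age_mean: float = 62.0
    age_sd: float = 16.0
    age_bounds: tuple[float, float] = (18.0, 95.0)
    comorbidity_prevalences: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PREVALENCES)
    )
    comorbidity_z_shifts: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_Z_SHIFTS)
    )
    biomarker_shift_matrix: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_BIOMARKER_SHIFTS.items()}
    )
    elective_surgery_prevalence: float = 0.274
    accel_log_hr: float = float(np.log(2.0))
    apache_log_hr: float = 0.07
    target_mortality: float = 0.10
    discharge_median_days: float = 10.0
    discharge_log_sd: float = 0.8
    n_readmissions: int = 0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.age_bounds[0] >= self.age_bounds[1]:
            raise ValueError("age bounds must be ordered")
        for name, p in self.comorbidity_prevalences.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"prevalence for {name} outside [0, 1]")
        if not 0.0 < self.target_mortality < 1.0:
            raise ValueError("target_mortality must be in (0, 1)")


@dataclass(frozen=True)
class TrueParameters:
    """Ground truth of a generated cohort, for recovery tests."""

    accel_log_hr: float
    apache_log_hr: float
    baseline_hazard: float
    expected_mortality: float
    target_mortality: float


_STREAMS = (
    "ages", "comorbidities", "elective", "latent", "biomarkers",
    "apache", "discharge", "death", "readmit",
)


def _rngs(seed: int) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(len(_STREAMS))
    return {name: np.random.default_rng(child) for name, child in zip(_STREAMS, children)}


def _truncated_normal(rng, n, mean, sd, lo, hi):
    out = rng.normal(mean, sd, size=n)
    bad = (out < lo) | (out > hi)
    while bad.any():
        out[bad] = rng.normal(mean, sd, size=int(bad.sum()))
        bad = (out < lo) | (out > hi)
    return out


def _draw_biomarkers(rng, n, ages, z, flags, config) -> dict[str, np.ndarray]:
    """Lab values around age- and z-dependent means, ICU-shifted."""
    da = ages - 60.0
    cols = {
        "albumin": rng.normal(40.0 - 0.08 * da - 2.0 * z, 4.0, n),
        "creatinine": rng.normal(85.0 + 0.4 * da + 20.0 * z, 25.0, n),
        "glucose": rng.normal(7.0 + 0.02 * da + 0.8 * z, 1.8, n),
        "crp": np.exp(rng.normal(np.log(5.0) + 0.35 * z, 1.1, n)),
        "lymphocyte_pct": rng.normal(18.0 - 0.05 * da - 2.0 * z, 7.0, n),
        "mcv": rng.normal(90.0 + 0.05 * da + 1.5 * z, 4.5, n),
        "rdw": rng.normal(14.0 + 1.2 * z, 1.6, n),
        "alp": np.exp(rng.normal(np.log(85.0) + 0.12 * z, 0.45, n)),
        "wbc": rng.normal(11.0 + 1.2 * z, 4.0, n),
    }
    for comorbidity, shifts in config.biomarker_shift_matrix.items():
        mask = flags[comorbidity].astype(bool)
        for analyte, shift in shifts.items():
            cols[analyte] = cols[analyte] + shift * mask
    # clip into physiologic/assay ranges; canonical-unit panel invariants
    bounds = {
        "albumin": (10.0, 60.0), "creatinine": (20.0, 2000.0), "glucose": (2.0, 40.0),
        "crp": (0.0, 60.0), "lymphocyte_pct": (0.5, 70.0), "mcv": (60.0, 130.0),
        "rdw": (11.0, 30.0), "alp": (15.0, 2000.0), "wbc": (0.5, 80.0),
    }
    return {k: np.clip(v, *bounds[k]) for k, v in cols.items()}


def _expected_mortality(h0, log_rel_hazard, discharge):
    h = h0 * np.exp(log_rel_hazard)
    return float(np.mean(-np.expm1(-h * discharge)))


def _tune_baseline(log_rel_hazard, discharge, target) -> float:
    """Bisect h0 so mean P(death before discharge) equals the target."""
    lo, hi = 1e-10, 10.0
    if _expected_mortality(hi, log_rel_hazard, discharge) < target:
        raise ValueError("target_mortality unattainable: bisection fails to bracket")
    for _ in range(200):
        mid = np.sqrt(lo * hi)  # hazards live on a log scale
        if _expected_mortality(mid, log_rel_hazard, discharge) < target:
            lo = mid
        else:
            hi = mid
    return float(np.sqrt(lo * hi))


def _simulate(config: SimulationConfig) -> tuple[pd.DataFrame, TrueParameters]:
    rngs = _rngs(config.seed)
    n = config.n

    ages = _truncated_normal(
        rngs["ages"], n, config.age_mean, config.age_sd, *config.age_bounds
    )

    flags = {}
    for name in COMORBIDITIES:
        p = config.comorbidity_prevalences.get(name, 0.0)
        flags[name] = (rngs["comorbidities"].random(n) < p).astype(int)
    elective = (rngs["elective"].random(n) < config.elective_surgery_prevalence).astype(int)

    z = rngs["latent"].normal(0.0, 1.0, n)
    for name in COMORBIDITIES:
        z = z + config.comorbidity_z_shifts.get(name, 0.0) * flags[name]

    biomarkers = _draw_biomarkers(rngs["biomarkers"], n, ages, z, flags, config)

    apache = np.rint(
        rngs["apache"].normal(15.0 + 0.06 * (ages - 60.0) + 2.5 * z - 3.0 * elective, 5.5, n)
    )
    apache = np.clip(apache, 0, 71).astype(int)

    discharge = np.exp(
        rngs["discharge"].normal(np.log(config.discharge_median_days), config.discharge_log_sd, n)
    )

    log_rel = config.accel_log_hr * (z > 0) + config.apache_log_hr * (apache - 15.0)
    h0 = _tune_baseline(log_rel, discharge, config.target_mortality)
    expected = _expected_mortality(h0, log_rel, discharge)

    hazards = h0 * np.exp(log_rel)
    death_time = rngs["death"].exponential(1.0, n) / hazards
    died = death_time < discharge
    time_days = np.where(died, death_time, discharge)

    table = pd.DataFrame({
        "patient_id": [f"P{i:06d}" for i in range(n)],
        "hospitalization_id": [f"H{i:06d}" for i in range(n)],
        "admission_order": np.ones(n, dtype=int),
        "age_years": ages,
    })
    from .phenoage import PANEL_COLUMNS
    for name, col in PANEL_COLUMNS.items():
        table[col] = biomarkers[name]
    for name in COMORBIDITIES:
        table[name] = flags[name]
    table["elective_surgery"] = elective
    table["apache_ii"] = apache
    table["died_in_hospital"] = died.astype(int)
    table["time_days"] = np.maximum(time_days, 1e-6)
    table["latent_accel"] = z

    if config.n_readmissions > 0:
        # extra later admissions within already-seen hospitalizations, for
        # exercising the first-admission inclusion filter
        idx = rngs["readmit"].choice(n, size=config.n_readmissions, replace=False)
        extra = table.iloc[idx].copy().reset_index(drop=True)
        extra["patient_id"] = [f"R{i:06d}" for i in range(len(extra))]
        extra["admission_order"] = 2
        table = pd.concat([table, extra], ignore_index=True)

    truth = TrueParameters(
        accel_log_hr=config.accel_log_hr,
        apache_log_hr=config.apache_log_hr,
        baseline_hazard=h0,
        expected_mortality=expected,
        target_mortality=config.target_mortality,
    )
    return table, truth


def generate_cohort(config: SimulationConfig) -> pd.DataFrame:
    """Generate a synthetic ICU cohort; byte-identical given the same config."""
    table, _ = _simulate(config)
    return table


def true_parameters(config: SimulationConfig) -> TrueParameters:
    """Ground-truth log hazard ratios and tuned baseline for a config."""
    _, truth = _simulate(config)
    return truth
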