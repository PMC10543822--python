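"""Cohort recalibration of PhenoAge: age gap, residuals, acceleration flag.

Three related measures of "biologically older than expected":

(a) the signed age gap, PhenoAge minus chronological age;
(b) the residual from an ordinary least-squares regression of PhenoAge on
    chronological age fitted over the whole cohort — this indexes each
    patient to the other patients in the same context, a within-cohort
    recalibration;
(c) PhenoAgeAccel, a dichotomous flag set when that residual is strictly
    positive.

Because the clock includes chronological age as a predictor, PhenoAge
diverges upward with age; the regression residual removes that systematic
divergence. The fitted intercept is the cohort-specific excess PhenoAge at
which acceleration begins.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = ["RecalibrationFit", "age_gap", "fit_age_regression", "classify_phenoage_accel", "augment_cohort"]


@dataclass(frozen=True)
class RecalibrationFit:
    """OLS of PhenoAge (response) on chronological age (single predictor)."""

    slope: float
    intercept: float
    residuals: np.ndarray
    accel_flags: np.ndarray
    n: int


def age_gap(phenoage, age):
    """Signed difference PhenoAge minus chronological age, in years."""
    return np.asarray(phenoage, dtype=float) - np.asarray(age, dtype=float)


def fit_age_regression(phenoages, ages) -> RecalibrationFit:
    """Fit PhenoAge ~ chronological age by OLS over the whole cohort.

    Residual_i = phenoage_i - (intercept + slope * age_i); the acceleration
    flag is residual > 0 (a residual of exactly zero is not accelerated).

    Raises ``ValueError`` on length mismatch, n < 2, or a degenerate design
    (all ages identical).
    """
    y = np.asarray(phenoages, dtype=float)
    x = np.asarray(ages, dtype=float)
    if y.shape != x.shape or y.ndim != 1:
        raise ValueError("phenoages and ages must be 1-d arrays of equal length")
    if len(x) < 2:
        raise ValueError("need at least two patients to fit the regression")
    if np.ptp(x) == 0:
        raise ValueError("degenerate design: all chronological ages are equal")
    model = sm.OLS(y, sm.add_constant(x)).fit()
    intercept, slope = model.params
    residuals = y - (intercept + slope * x)
    return RecalibrationFit(
        slope=float(slope),
        intercept=float(intercept),
        residuals=residuals,
        accel_flags=residuals > 0,
        n=len(x),
    )


def classify_phenoage_accel(fit: RecalibrationFit) -> tuple[np.ndarray, float]:
    """Return the per-patient acceleration flags and the cohort intercept.

    The intercept is the cohort's summary "excess PhenoAge at which
    acceleration begins": a patient is flagged when their PhenoAge exceeds
    intercept + slope * age, i.e. when their gap over the fitted line is
    positive.
    """
    return fit.accel_flags, fit.intercept


def augment_cohort(cohort: pd.DataFrame, phenoages=None) -> tuple[pd.DataFrame, RecalibrationFit]:
    """Append the recalibration columns to a cohort table.

    Adds ``phenoage_years``, ``age_gap_years``, ``accel_residual_years``
    and ``phenoage_accel`` (0/1). If ``phenoages`` is None the table must
    already carry ``phenoage_years``.
    """
    out = cohort.copy()
    if phenoages is not None:
        out["phenoage_years"] = np.asarray(phenoages, dtype=float)
    fit = fit_age_regression(out["phenoage_years"], out["age_years"])
    out["age_gap_years"] = age_gap(out["phenoage_years"], out["age_years"])
    out["accel_residual_years"] = fit.residuals
    out["phenoage_accel"] = fit.accel_flags.astype(int)
    return out, fit
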