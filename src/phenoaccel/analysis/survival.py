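"""Cox proportional-hazards fits, the sequential adjustment ladder, and
survival curves (Kaplan–Meier and mean-covariate adjusted).

Hospital death is the event; survivors are censored at discharge. Partial
likelihood is maximised with Efron tie handling (ties at day resolution are
common in hospital data). The sequential ladder re-fits a nested sequence
of models, adding one configured adjuster per step in a fixed order and
reporting the focal covariate's hazard ratio at each step; an optional
entry-p mode admits an adjuster only when its own Wald p-value passes a
threshold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test

log = logging.getLogger("phenoaccel")

__all__ = [
    "CoxModel", "cox_fit", "sequential_cox", "LadderRow", "CoxLadder",
    "km_curves", "adjusted_survival_curves",
]


@dataclass(frozen=True)
class CoxModel:
    names: list[str]
    coefficients: np.ndarray        # log hazard ratios
    standard_errors: np.ndarray
    hazard_ratios: np.ndarray
    ci_low: np.ndarray              # HR scale, 95%
    ci_high: np.ndarray
    p_values: np.ndarray
    concordance: float              # Harrell's C of the fitted risk score
    log_likelihood: float           # log partial likelihood at the optimum
    covariance: np.ndarray          # of the coefficients
    n: int
    n_events: int


def _fit_cph(df: pd.DataFrame) -> CoxPHFitter:
    """Fit lifelines on a frame with _time/_event columns.

    Near-separation (rare binary covariates with few events) can halt
    Newton-Raphson; a light ridge penalty is the standard remedy and the
    retry is logged so the fit is auditable.
    """
    opts = {"precision": 1e-9, "max_steps": 500}
    cph = CoxPHFitter()
    try:
        cph.fit(df, duration_col="_time", event_col="_event", fit_options=opts)
        return cph
    except Exception as first_exc:  # lifelines ConvergenceError and kin
        log.warning("Cox fit did not converge unpenalized (%s); "
                    "retrying with L2 penalty 0.01", first_exc)
        cph = CoxPHFitter(penalizer=0.01, l1_ratio=0.0)
        try:
            cph.fit(df, duration_col="_time", event_col="_event", fit_options=opts)
            return cph
        except Exception as exc:
            raise RuntimeError(f"Cox fit failed to converge: {exc}") from exc


def cox_fit(times, events, covariates, names=None) -> CoxModel:
    """Maximum partial likelihood Cox fit (Efron ties), Wald 95% CIs.

    ``covariates`` is an (n, p) matrix. Zero-variance columns carry no
    information: their coefficient is reported as 0 (HR 1) with infinite
    standard error, and the model is fitted on the remaining columns.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events).astype(int)
    X = np.atleast_2d(np.asarray(covariates, dtype=float))
    if X.shape[0] != len(times):
        X = X.T
    if names is None:
        names = [f"x{j}" for j in range(X.shape[1])]
    names = list(names)
    if events.sum() == 0:
        raise ValueError("no events: Cox model cannot be fitted")
    if np.isnan(X).any() or np.isnan(times).any():
        raise ValueError("missing values in times or covariates")

    constant = [j for j in range(X.shape[1]) if np.ptp(X[:, j]) == 0]
    active = [j for j in range(X.shape[1]) if j not in constant]

    p = X.shape[1]
    coefs = np.zeros(p)
    ses = np.full(p, np.inf)
    pvals = np.ones(p)
    cov = np.zeros((p, p))

    if active:
        df = pd.DataFrame(X[:, active], columns=[names[j] for j in active])
        df["_time"] = times
        df["_event"] = events
        cph = _fit_cph(df)
        for k, j in enumerate(active):
            name = names[j]
            coefs[j] = cph.params_[name]
            ses[j] = cph.standard_errors_[name]
            pvals[j] = cph.summary.loc[name, "p"]
        sub = cph.variance_matrix_.to_numpy()
        for a, ja in enumerate(active):
            for b, jb in enumerate(active):
                cov[ja, jb] = sub[a, b]
        concordance_val = float(cph.concordance_index_)
        loglik = float(cph.log_likelihood_)
    else:
        # null model: concordance of a constant score is 0.5 by convention
        concordance_val = 0.5
        loglik = _null_log_partial_likelihood(times, events)

    z = 1.959963984540054
    with np.errstate(over="ignore"):
        hr = np.exp(coefs)
        ci_low = np.exp(coefs - z * ses)
        ci_high = np.exp(coefs + z * ses)
    return CoxModel(
        names=names, coefficients=coefs, standard_errors=ses,
        hazard_ratios=hr, ci_low=ci_low, ci_high=ci_high, p_values=pvals,
        concordance=concordance_val, log_likelihood=loglik, covariance=cov,
        n=len(times), n_events=int(events.sum()),
    )


def _null_log_partial_likelihood(times, events) -> float:
    """Efron log partial likelihood with all coefficients zero."""
    order = np.argsort(times)
    t, e = times[order], events[order]
    ll = 0.0
    i = 0
    n = len(t)
    at_risk = n
    while i < n:
        j = i
        d = 0
        while j < n and t[j] == t[i]:
            d += int(e[j])
            j += 1
        # at beta = 0 the Efron denominators reduce to at_risk - r
        for r in range(d):
            ll -= np.log(at_risk - r)
        at_risk -= j - i
        i = j
    return float(ll)


@dataclass(frozen=True)
class LadderRow:
    model_terms: list[str]
    focal_hr: float
    ci_low: float
    ci_high: float
    p_value: float
    n_used: int
    n_excluded_missing: int


@dataclass(frozen=True)
class CoxLadder:
    focal: str
    rows: list[LadderRow]
    final_model: CoxModel
    final_n_excluded_missing: int


def _complete_case(cohort: pd.DataFrame, cols: list[str], time_col, event_col):
    used = cohort[cols + [time_col, event_col]]
    mask = used.notna().all(axis=1)
    return cohort.loc[mask], int((~mask).sum())


def sequential_cox(
    cohort: pd.DataFrame,
    focal: str,
    ordered_adjusters: list[str],
    time_col: str = "time_days",
    event_col: str = "died_in_hospital",
    entry_p_threshold: float | None = None,
) -> CoxLadder:
    """Nested Cox ladder: focal alone, then + one adjuster per step.

    Step k fits focal + the first k adjusters exactly in the given order and
    records the focal covariate's hazard ratio; the last step is also
    reported covariate-by-covariate as the final full model. Rows with
    missing values in the covariates a step uses are dropped for that step
    (complete-case), with the exclusion count recorded.

    With ``entry_p_threshold`` set, an adjuster is entered only if its own
    Wald p-value in the candidate model is below the threshold (a stepwise
    forward mode); by default every adjuster is forced in, one per step.
    """
    if focal not in cohort.columns:
        raise ValueError(f"focal covariate {focal!r} not in cohort")
    for a in ordered_adjusters:
        if a not in cohort.columns:
            raise ValueError(f"adjuster {a!r} not in cohort")

    rows: list[LadderRow] = []
    entered: list[str] = []

    def fit_step(terms: list[str]):
        data, n_missing = _complete_case(cohort, terms, time_col, event_col)
        model = cox_fit(
            data[time_col], data[event_col], data[terms].to_numpy(), names=terms
        )
        return model, len(data), n_missing

    model, n_used, n_missing = fit_step([focal])
    rows.append(LadderRow([focal], model.hazard_ratios[0], model.ci_low[0],
                          model.ci_high[0], model.p_values[0], n_used, n_missing))

    for adjuster in ordered_adjusters:
        candidate = [focal] + entered + [adjuster]
        model, n_used, n_missing = fit_step(candidate)
        if entry_p_threshold is not None:
            j = candidate.index(adjuster)
            if model.p_values[j] >= entry_p_threshold:
                continue
        entered.append(adjuster)
        rows.append(LadderRow(list(candidate), model.hazard_ratios[0], model.ci_low[0],
                              model.ci_high[0], model.p_values[0], n_used, n_missing))

    final_terms = [focal] + entered
    final_model, _, final_missing = fit_step(final_terms)
    return CoxLadder(focal=focal, rows=rows, final_model=final_model,
                     final_n_excluded_missing=final_missing)


def km_curves(times, events, groups) -> dict:
    """Kaplan–Meier survival per group plus a log-rank comparison."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events).astype(int)
    groups = np.asarray(groups)
    curves = {}
    for g in np.unique(groups):
        mask = groups == g
        kmf = KaplanMeierFitter()
        kmf.fit(times[mask], events[mask], label=str(g))
        sf = kmf.survival_function_
        curves[str(g)] = pd.DataFrame(
            {"time_days": sf.index.to_numpy(), "survival": sf.iloc[:, 0].to_numpy()}
        )
    levels = np.unique(groups)
    p = None
    if len(levels) == 2:
        a, b = (groups == levels[0]), (groups == levels[1])
        p = float(logrank_test(times[a], times[b], events[a], events[b]).p_value)
    return {"curves": curves, "logrank_p": p}


def adjusted_survival_curves(
    cohort: pd.DataFrame,
    focal: str,
    adjusters: list[str],
    time_col: str = "time_days",
    event_col: str = "died_in_hospital",
) -> dict:
    """Covariate-adjusted curves by the mean-covariate method.

    Fits the full Cox model and predicts the survival function for a
    synthetic patient at the cohort means of all adjusters, with the focal
    indicator set to 0 and to 1.
    """
    terms = [focal] + list(adjusters)
    data, _ = _complete_case(cohort, terms, time_col, event_col)
    df = data[terms].copy()
    df["_time"] = data[time_col].to_numpy(dtype=float)
    df["_event"] = data[event_col].to_numpy(dtype=int)
    # drop uninformative constant columns (e.g. an absent comorbidity)
    terms = [t for t in terms if df[t].nunique() > 1 or t == focal]
    df = df[terms + ["_time", "_event"]]
    cph = _fit_cph(df)
    means = df[terms].mean()
    out = {}
    for level in (0, 1):
        profile = means.copy()
        profile[focal] = level
        sf = cph.predict_survival_function(profile.to_frame().T)
        out[str(level)] = pd.DataFrame(
            {"time_days": sf.index.to_numpy(), "survival": sf.iloc[:, 0].to_numpy()}
        )
    return out
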