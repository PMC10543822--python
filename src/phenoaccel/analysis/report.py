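"""Assemble the full mortality-analysis report for a scored cohort.

One call runs the whole statistical battery on a cohort that already
carries the PhenoAge and recalibration columns: descriptive group
comparisons, AUROC discrimination of age versus the clock measures, the
sequential Cox adjustment ladder ending in a full model with the
APACHE II > 15 indicator, the 4-knot spline dose–response curve for the
acceleration residual, comorbidity odds ratios for the acceleration flag,
survival curves, and the AUROC power block.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ..simulate import COMORBIDITIES
from .roc import auroc, compare_auroc
from .survival import CoxLadder, adjusted_survival_curves, km_curves, sequential_cox
from .splines import SplineCurve, spline_hazard_curve
from .tables import comorbidity_odds, percent, table_one
from .power import auroc_sample_size

__all__ = ["AnalysisReport", "build_report", "write_report", "LADDER_ADJUSTERS"]

#: Adjuster entry order for the sequential Cox ladder: demographics and the
#: chronic-health flags first, severity of acute illness last.
LADDER_ADJUSTERS = [
    "age_years",
    "elective_surgery",
    "chronic_respiratory",
    "chronic_cardiovascular",
    "cirrhosis",
    "end_stage_renal_failure",
    "immune_disease",
    "immunosuppressed",
    "aids",
    "lymphoma",
    "metastatic_cancer",
    "leukemia",
    "diabetes",
    "apache_gt15",
]

ROC_SCORES = ["age_years", "phenoage_years", "age_gap_years", "accel_residual_years"]


@dataclass
class AnalysisReport:
    counts: dict
    table_one_rows: list[dict]
    roc: dict[str, dict]
    roc_comparisons: list[dict]
    ladder: CoxLadder
    spline: SplineCurve
    comorbidity_or: list[dict]
    power: dict
    km: dict
    adjusted_curves: dict = field(default_factory=dict)


def _counts(cohort: pd.DataFrame) -> dict:
    n = len(cohort)
    deaths = int(cohort["died_in_hospital"].sum())
    accel = int(cohort["phenoage_accel"].sum())
    accel_dead = int(cohort.loc[cohort["died_in_hospital"] == 1, "phenoage_accel"].sum())
    return {
        "n": n,
        "deaths": deaths,
        "hospital_mortality_pct": percent(deaths, n),
        "accel_n": accel,
        "accel_prevalence_pct": percent(accel, n),
        "accel_among_nonsurvivors_pct": percent(accel_dead, deaths) if deaths else None,
    }


def build_report(
    cohort: pd.DataFrame,
    adjusters: list[str] | None = None,
    apache_cut: int = 15,
    power_targets: tuple[float, ...] = (0.60, 0.65),
    neg_pos_ratio: float = 10.0,
    with_adjusted_curves: bool = True,
) -> AnalysisReport:
    """Run every analysis section on a scored, recalibrated cohort."""
    cohort = cohort.copy()
    cohort["apache_gt15"] = (cohort["apache_ii"] > apache_cut).astype(int)
    if adjusters is None:
        adjusters = [a for a in LADDER_ADJUSTERS if a in cohort.columns]

    labels = cohort["died_in_hospital"].to_numpy(dtype=int)

    categorical = ["phenoage_accel", "elective_surgery", "apache_gt15"] + [
        c for c in COMORBIDITIES if c in cohort.columns
    ]
    continuous = [c for c in ["age_years", "phenoage_years", "age_gap_years",
                              "accel_residual_years", "apache_ii"] if c in cohort.columns]
    t1 = table_one(cohort, categorical=categorical, continuous=continuous)

    roc = {}
    for score in ROC_SCORES + ["phenoage_accel", "apache_ii"]:
        if score in cohort.columns:
            roc[score] = vars(auroc(cohort[score].to_numpy(dtype=float), labels))
    comparisons = []
    for other in ("phenoage_years", "age_gap_years", "accel_residual_years"):
        if other in cohort.columns:
            res = compare_auroc(
                cohort[other].to_numpy(dtype=float),
                cohort["age_years"].to_numpy(dtype=float),
                labels,
            )
            res["scores"] = (other, "age_years")
            comparisons.append(res)

    ladder = sequential_cox(cohort, focal="phenoage_accel", ordered_adjusters=adjusters)

    spline = spline_hazard_curve(
        cohort["time_days"].to_numpy(dtype=float),
        labels,
        cohort["accel_residual_years"].to_numpy(dtype=float),
    )

    odds = comorbidity_odds(cohort, [c for c in COMORBIDITIES if c in cohort.columns])

    power = {}
    for theta in power_targets:
        n_pos, n_total = auroc_sample_size(theta, neg_pos_ratio=neg_pos_ratio)
        power[f"auc_{theta:g}"] = {"n_pos": n_pos, "n_total": n_total,
                                   "alpha": 0.05, "power": 0.80,
                                   "neg_pos_ratio": neg_pos_ratio}

    km = km_curves(cohort["time_days"], labels, cohort["phenoage_accel"])
    adj = {}
    if with_adjusted_curves:
        adj = adjusted_survival_curves(cohort, "phenoage_accel", adjusters)

    return AnalysisReport(
        counts=_counts(cohort),
        table_one_rows=t1,
        roc=roc,
        roc_comparisons=comparisons,
        ladder=ladder,
        spline=spline,
        comorbidity_or=odds,
        power=power,
        km=km,
        adjusted_curves=adj,
    )


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return [_jsonable(v) for v in obj.tolist()]
    if isinstance(obj, (np.floating, float)):
        v = float(obj)
        return v if np.isfinite(v) else None
    if isinstance(obj, (np.integer, int, bool)) or obj is None or isinstance(obj, str):
        return int(obj) if isinstance(obj, np.integer) else obj
    return str(obj)


def report_to_dict(report: AnalysisReport) -> dict:
    """Structured (JSON-ready) rendering of every report section."""
    ladder_rows = [
        {"model_terms": r.model_terms, "focal_hr": r.focal_hr,
         "ci_low": r.ci_low, "ci_high": r.ci_high, "p_value": r.p_value,
         "n_used": r.n_used, "n_excluded_missing": r.n_excluded_missing}
        for r in report.ladder.rows
    ]
    fm = report.ladder.final_model
    final_rows = [
        {"covariate": name, "hr": fm.hazard_ratios[j], "ci_low": fm.ci_low[j],
         "ci_high": fm.ci_high[j], "p_value": fm.p_values[j]}
        for j, name in enumerate(fm.names)
    ]
    return _jsonable({
        "counts": report.counts,
        "table_one": report.table_one_rows,
        "roc": report.roc,
        "roc_comparisons": report.roc_comparisons,
        "cox_ladder": ladder_rows,
        "final_model": final_rows,
        "final_model_concordance": fm.concordance,
        "spline": {
            "knots": report.spline.knots,
            "coefficients": report.spline.coefficients,
            "nonlinearity_p": report.spline.nonlinearity_p,
        },
        "comorbidity_odds": report.comorbidity_or,
        "power": report.power,
        "km_logrank_p": report.km["logrank_p"],
    })


def _fmt(v, spec=".3f") -> str:
    return format(v, spec) if isinstance(v, (int, float)) else "--"


def _render_text(d: dict) -> str:
    lines = ["Cohort analysis report", "======================", ""]
    c = d["counts"]
    lines.append(f"Patients: {c['n']}  deaths: {c['deaths']} "
                 f"({c['hospital_mortality_pct']}%)  "
                 f"accelerated: {c['accel_n']} ({c['accel_prevalence_pct']}%)")
    lines.append("")
    lines.append("AUROC for hospital mortality")
    for name, r in d["roc"].items():
        lines.append(f"  {name:24s} {r['auc']:.3f} ({r['ci_low']:.3f}-{r['ci_high']:.3f})")
    lines.append("")
    lines.append("Sequential Cox ladder (focal: phenoage_accel)")
    for row in d["cox_ladder"]:
        terms = " + ".join(row["model_terms"])
        lines.append(f"  HR {_fmt(row['focal_hr'])} ({_fmt(row['ci_low'])}-{_fmt(row['ci_high'])})"
                     f"  p={_fmt(row['p_value'], '.3g')}  [{terms}]")
    lines.append("")
    lines.append("Final full model")
    for row in d["final_model"]:
        lines.append(f"  {row['covariate']:24s} HR {_fmt(row['hr'])} "
                     f"({_fmt(row['ci_low'])}-{_fmt(row['ci_high'])})  p={_fmt(row['p_value'], '.3g')}")
    lines.append(f"  Harrell's C: {_fmt(d['final_model_concordance'])}")
    lines.append("")
    lines.append("Comorbidity odds ratios for acceleration")
    for row in d["comorbidity_odds"]:
        lines.append(f"  {row['comorbidity']:24s} OR {_fmt(row['odds_ratio'])} "
                     f"({_fmt(row['ci_low'])}-{_fmt(row['ci_high'])})  p={_fmt(row['p_value'], '.3g')}")
    lines.append("")
    lines.append("AUROC power calculation")
    for name, row in d["power"].items():
        lines.append(f"  {name}: n_pos={row['n_pos']} n_total={row['n_total']}")
    lines.append("")
    lines.append(f"Spline nonlinearity p: {d['spline']['nonlinearity_p']}")
    lines.append(f"Log-rank p (accel vs not): {d['km_logrank_p']}")
    return "\n".join(lines) + "\n"


def write_report(report: AnalysisReport, out_dir: str | Path) -> Path:
    """Write JSON, plain-text tables, and curve CSV grids to a directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    d = report_to_dict(report)
    (out / "report.json").write_text(json.dumps(d, indent=2, sort_keys=True))
    (out / "report.txt").write_text(_render_text(d))
    spline_df = pd.DataFrame({
        "residual_years": report.spline.grid,
        "log_hr": report.spline.log_hr,
        "ci_low": report.spline.ci_low,
        "ci_high": report.spline.ci_high,
    })
    spline_df.to_csv(out / "spline_curve.csv", index=False, float_format="%.6g")
    for label, curve in report.km["curves"].items():
        curve.to_csv(out / f"km_accel_{label}.csv", index=False, float_format="%.6g")
    for label, curve in report.adjusted_curves.items():
        curve.to_csv(out / f"adjusted_accel_{label}.csv", index=False, float_format="%.6g")
    return out / "report.json"
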