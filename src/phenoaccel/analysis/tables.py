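"""Descriptive comparisons and comorbidity odds ratios.

Categorical variables are compared between hospital survivors and
non-survivors with Pearson's chi-square (no continuity correction);
continuous variables with the two-sided Mann–Whitney test, summarised as
median (IQR) per group. Comorbidity–acceleration associations are 2x2 odds
ratios with Woolf logit confidence intervals.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency, mannwhitneyu, norm

__all__ = ["percent", "table_one", "comorbidity_odds", "odds_ratio_2x2"]


def percent(count: int, total: int, ndigits: int = 1) -> float:
    """Percentage of ``count`` out of ``total``, rounded for reporting."""
    if total <= 0:
        raise ValueError("total must be positive")
    return round(100.0 * count / total, ndigits)


def _median_iqr(x: np.ndarray) -> tuple[float, float, float]:
    q1, med, q3 = np.percentile(x, [25, 50, 75])
    return float(med), float(q1), float(q3)


def table_one(
    cohort: pd.DataFrame,
    categorical: list[str],
    continuous: list[str],
    group_col: str = "died_in_hospital",
) -> list[dict]:
    """Compare every variable between the two outcome groups.

    Returns one row per variable: counts/percentages and chi-square p for
    categorical variables, median (IQR) per group and Mann–Whitney p for
    continuous ones. A variable constant in both groups has no chi-square
    statistic and is flagged and skipped.
    """
    g = cohort[group_col].astype(int)
    if (g == 0).sum() == 0 or (g == 1).sum() == 0:
        raise ValueError("both outcome groups must be non-empty")
    rows = []
    for var in categorical:
        x = cohort[var]
        mask = x.notna()
        xv, gv = x[mask].astype(int), g[mask]
        table = pd.crosstab(xv, gv)
        if table.shape[0] < 2:
            rows.append({"variable": var, "type": "categorical",
                         "skipped": True, "reason": "constant in both groups"})
            continue
        stat, p, _, _ = chi2_contingency(table.to_numpy(), correction=False)
        n0, n1 = int((gv == 0).sum()), int((gv == 1).sum())
        c0 = int(((xv == 1) & (gv == 0)).sum())
        c1 = int(((xv == 1) & (gv == 1)).sum())
        rows.append({
            "variable": var, "type": "categorical", "skipped": False,
            "count_survivors": c0, "pct_survivors": percent(c0, n0),
            "count_nonsurvivors": c1, "pct_nonsurvivors": percent(c1, n1),
            "statistic": float(stat), "p_value": float(p),
        })
    for var in continuous:
        x = cohort[var].astype(float)
        mask = x.notna()
        a = x[mask & (g == 0)].to_numpy()
        b = x[mask & (g == 1)].to_numpy()
        stat, p = mannwhitneyu(a, b, alternative="two-sided")
        med0, q10, q30 = _median_iqr(a)
        med1, q11, q31 = _median_iqr(b)
        rows.append({
            "variable": var, "type": "continuous", "skipped": False,
            "median_survivors": med0, "iqr_survivors": (q10, q30),
            "median_nonsurvivors": med1, "iqr_nonsurvivors": (q11, q31),
            "statistic": float(stat), "p_value": float(p),
        })
    return rows


def odds_ratio_2x2(a: int, b: int, c: int, d: int, alpha: float = 0.05) -> dict:
    """Odds ratio ad/bc with Woolf logit CI and chi-square p.

    Cells: a = exposed & flagged, b = exposed & not, c = unexposed &
    flagged, d = unexposed & not. Any zero cell triggers the
    Haldane–Anscombe 0.5 correction, flagged in the output.
    """
    cells = np.array([a, b, c, d], dtype=float)
    if (cells < 0).any():
        raise ValueError("cell counts must be non-negative")
    corrected = bool((cells == 0).any())
    a2, b2, c2, d2 = cells + 0.5 if corrected else cells
    oratio = (a2 * d2) / (b2 * c2)
    se = np.sqrt(1 / a2 + 1 / b2 + 1 / c2 + 1 / d2)
    z = norm.ppf(1 - alpha / 2)
    table = np.array([[a, b], [c, d]], dtype=float)
    if corrected:
        table = table + 0.5
    stat, p, _, _ = chi2_contingency(table, correction=False)
    return {
        "odds_ratio": float(oratio),
        "ci_low": float(np.exp(np.log(oratio) - z * se)),
        "ci_high": float(np.exp(np.log(oratio) + z * se)),
        "p_value": float(p),
        "zero_cell_corrected": corrected,
    }


def comorbidity_odds(
    cohort: pd.DataFrame,
    comorbidities: list[str],
    flag_col: str = "phenoage_accel",
) -> list[dict]:
    """Odds of the acceleration flag per comorbidity (complete-case)."""
    rows = []
    flag = cohort[flag_col]
    for var in comorbidities:
        x = cohort[var]
        mask = x.notna() & flag.notna()
        xv = x[mask].astype(int)
        fv = flag[mask].astype(int)
        a = int(((xv == 1) & (fv == 1)).sum())
        b = int(((xv == 1) & (fv == 0)).sum())
        c = int(((xv == 0) & (fv == 1)).sum())
        d = int(((xv == 0) & (fv == 0)).sum())
        row = {"comorbidity": var, "n_used": int(mask.sum())}
        row.update(odds_ratio_2x2(a, b, c, d))
        rows.append(row)
    return rows
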