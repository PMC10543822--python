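"""Levine PhenoAge: biological age from nine routine blood tests.

The clock maps chronological age plus nine blood biomarkers through a
weighted linear predictor ``xb``, a Gompertz 10-year mortality risk

    M = 1 - exp(-exp(xb) * (exp(gamma * t) - 1) / gamma),   t = 120 months,

and an inverse Gompertz transform back onto an age scale (years):

    PhenoAge = c + ln(a * ln(1 - M)) / b,   a < 0 so the log argument is > 0.

Coefficients are unit-specific (albumin g/L, creatinine umol/L, glucose
mmol/L, CRP mg/dL entering as ln(CRP), lymphocyte % of WBC, MCV fL, RDW %,
ALP U/L, WBC 10^9/L) and live in a versioned JSON constants file so an
alternative transcription can be dropped in without touching code.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, replace
from importlib import resources
from typing import Mapping

import numpy as np

__all__ = [
    "BIOMARKERS",
    "BiomarkerPanel",
    "PhenoAgeCoefficients",
    "PhenoAgeResult",
    "load_coefficients",
    "validate_panel",
    "linear_predictor",
    "mortality_risk",
    "phenoage_from_risk",
    "compute_phenoage",
    "score_dataframe",
    "PanelValidationError",
]

#: Canonical biomarker order; also the order of the CSV panel columns.
BIOMARKERS = (
    "albumin",
    "creatinine",
    "glucose",
    "crp",
    "lymphocyte_pct",
    "mcv",
    "rdw",
    "alp",
    "wbc",
)

#: CSV column name per biomarker (canonical units encoded in the name).
PANEL_COLUMNS = {
    "albumin": "albumin_g_l",
    "creatinine": "creatinine_umol_l",
    "glucose": "glucose_mmol_l",
    "crp": "crp_mg_dl",
    "lymphocyte_pct": "lymphocyte_pct",
    "mcv": "mcv_fl",
    "rdw": "rdw_pct",
    "alp": "alp_u_l",
    "wbc": "wbc_10e9_l",
}

#: Accepted unit dialects: (analyte, unit code) -> multiplicative factor to
#: canonical units. Silent unit mismatch is the dominant failure mode for
#: unit-specific clock coefficients, hence the explicit table.
UNIT_FACTORS = {
    ("albumin", "g/L"): 1.0,
    ("albumin", "g/dL"): 10.0,
    ("creatinine", "umol/L"): 1.0,
    ("creatinine", "mg/dL"): 88.42,
    ("glucose", "mmol/L"): 1.0,
    ("glucose", "mg/dL"): 1.0 / 18.016,
    ("crp", "mg/dL"): 1.0,
    ("crp", "mg/L"): 0.1,
    ("lymphocyte_pct", "%"): 1.0,
    ("mcv", "fL"): 1.0,
    ("rdw", "%"): 1.0,
    ("alp", "U/L"): 1.0,
    ("wbc", "10^9/L"): 1.0,
    ("wbc", "10^3/uL"): 1.0,
}


class PanelValidationError(ValueError):
    """A biomarker value violates the panel invariants; names the analyte."""


@dataclass(frozen=True)
class BiomarkerPanel:
    """One patient's nine blood values in canonical units.

    albumin g/L, creatinine umol/L, glucose mmol/L, crp mg/dL,
    lymphocyte_pct % of WBC, mcv fL, rdw %, alp U/L, wbc 10^9/L.
    """

    albumin: float
    creatinine: float
    glucose: float
    crp: float
    lymphocyte_pct: float
    mcv: float
    rdw: float
    alp: float
    wbc: float

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in BIOMARKERS}


@dataclass(frozen=True)
class PhenoAgeCoefficients:
    """Constants of the PhenoAge transform chain.

    ``weights`` maps biomarker name to its linear-predictor weight (the crp
    weight applies to ln(crp)); ``gompertz_gamma`` is per month;
    ``inv_a/inv_b/inv_c`` are the inverse-Gompertz age-scale constants.
    """

    intercept: float
    weights: Mapping[str, float]
    age_weight: float
    gompertz_gamma: float
    horizon_months: float = 120.0
    inv_a: float = -0.00553
    inv_b: float = 0.09165
    inv_c: float = 141.50225
    name: str = "unnamed"

    def __post_init__(self) -> None:
        if self.gompertz_gamma <= 0:
            raise ValueError("gompertz_gamma must be positive")
        if self.horizon_months <= 0:
            raise ValueError("horizon_months must be positive")
        if self.inv_b <= 0:
            raise ValueError("inv_b must be positive")
        if self.inv_a >= 0:
            raise ValueError("inv_a must be negative")
        missing = set(BIOMARKERS) - set(self.weights)
        if missing:
            raise ValueError(f"missing weights for: {sorted(missing)}")


@dataclass(frozen=True)
class PhenoAgeResult:
    """Linear predictor, 10-year mortality risk and phenotypic age (years)."""

    xb: float
    mortality_risk: float
    phenoage: float


#: CRP floor (mg/dL) applied before taking ln; lab CRP is reported as 0 or
#: "below detection" for healthy patients and ln(0) is undefined.
CRP_FLOOR_MG_DL = 0.01

#: Two-sided clamp on the mortality risk so the age-scale inverse is finite.
RISK_EPS = 1e-12

_RANGES = {
    "albumin": (0.0, 100.0),
    "creatinine": (0.0, 5000.0),
    "glucose": (0.0, 100.0),
    "crp": (0.0, 200.0),
    "lymphocyte_pct": (0.0, 100.0),
    "mcv": (0.0, 200.0),
    "rdw": (0.0, 50.0),
    "alp": (0.0, 5000.0),
    "wbc": (0.0, 500.0),
}


def load_coefficients(path: str | None = None) -> PhenoAgeCoefficients:
    """Load a coefficients file; default is the shipped Levine constants.

    The file is flat JSON with one key per constant and a ``weights``
    mapping keyed by biomarker name.
    """
    if path is None:
        ref = resources.files("phenoaccel.constants") / "phenoage_levine_default.json"
        raw = json.loads(ref.read_text())
    else:
        with open(path) as fh:
            raw = json.load(fh)
    return PhenoAgeCoefficients(
        intercept=float(raw["intercept"]),
        weights={k: float(v) for k, v in raw["weights"].items()},
        age_weight=float(raw["age_weight"]),
        gompertz_gamma=float(raw["gompertz_gamma"]),
        horizon_months=float(raw.get("horizon_months", 120.0)),
        inv_a=float(raw.get("inv_a", -0.00553)),
        inv_b=float(raw.get("inv_b", 0.09165)),
        inv_c=float(raw.get("inv_c", 141.50225)),
        name=str(raw.get("name", "unnamed")),
    )


def convert_to_canonical(analyte: str, value: float, unit: str) -> float:
    """Convert a lab value to the canonical unit for its analyte."""
    key = (analyte, unit)
    if key not in UNIT_FACTORS:
        raise PanelValidationError(f"unresolvable unit {unit!r} for analyte {analyte!r}")
    return value * UNIT_FACTORS[key]


def validate_panel(panel: BiomarkerPanel, crp_floor: float = CRP_FLOOR_MG_DL) -> BiomarkerPanel:
    """Validate a canonical-unit panel, clamping CRP up to its floor.

    All values must be finite and strictly positive (CRP may be zero or
    below the floor before clamping); lymphocyte percentage must lie in
    (0, 100]. Violations raise :class:`PanelValidationError` naming the
    offending analyte.
    """
    values = panel.as_dict()
    for name, value in values.items():
        if not math.isfinite(value):
            raise PanelValidationError(f"{name}: non-finite value {value!r}")
        lo, hi = _RANGES[name]
        if name == "crp":
            if value < 0:
                raise PanelValidationError(f"crp: negative value {value!r}")
        elif value <= lo:
            raise PanelValidationError(f"{name}: value {value!r} must be > {lo}")
        if value > hi:
            raise PanelValidationError(f"{name}: value {value!r} out of range (> {hi})")
    if values["crp"] < crp_floor:
        return replace(panel, crp=crp_floor)
    return panel


def linear_predictor(
    panel: BiomarkerPanel, age: float, coeffs: PhenoAgeCoefficients
) -> float:
    """Weighted linear predictor xb; the crp term is ln(crp)."""
    if panel.crp <= 0:
        raise PanelValidationError("crp: must be positive after clamping (ln undefined)")
    xb = coeffs.intercept + coeffs.age_weight * age
    for name in BIOMARKERS:
        term = math.log(panel.crp) if name == "crp" else getattr(panel, name)
        xb += coeffs.weights[name] * term
    return xb


def mortality_risk(xb: float, coeffs: PhenoAgeCoefficients, eps: float = RISK_EPS) -> float:
    """Gompertz mortality risk over the horizon, clamped into [eps, 1-eps]."""
    g = coeffs.gompertz_gamma
    cum = (math.exp(g * coeffs.horizon_months) - 1.0) / g
    # exp(xb) can overflow for absurd inputs; the clamp absorbs both tails.
    try:
        m = 1.0 - math.exp(-math.exp(xb) * cum)
    except OverflowError:
        m = 1.0
    return min(max(m, eps), 1.0 - eps)


def phenoage_from_risk(m: float, coeffs: PhenoAgeCoefficients) -> float:
    """Invert the mortality risk onto the age scale (years)."""
    if not 0.0 < m < 1.0:
        raise ValueError(f"mortality risk must be in (0, 1); got {m!r}")
    return coeffs.inv_c + math.log(coeffs.inv_a * math.log1p(-m)) / coeffs.inv_b


def compute_phenoage(
    panel: BiomarkerPanel, age: float, coeffs: PhenoAgeCoefficients | None = None
) -> PhenoAgeResult:
    """Score one validated panel: xb -> mortality risk -> PhenoAge years."""
    if coeffs is None:
        coeffs = load_coefficients()
    xb = linear_predictor(panel, age, coeffs)
    m = mortality_risk(xb, coeffs)
    return PhenoAgeResult(xb=xb, mortality_risk=m, phenoage=phenoage_from_risk(m, coeffs))


def score_dataframe(df, coeffs: PhenoAgeCoefficients | None = None) -> "np.ndarray":
    """Vectorised PhenoAge for a cohort table using the canonical columns.

    Expects the panel columns of :data:`PANEL_COLUMNS` plus ``age_years``;
    returns an array of PhenoAge values (years), one per row. Each row is
    validated (CRP clamped) exactly as :func:`validate_panel` does.
    """
    if coeffs is None:
        coeffs = load_coefficients()
    out = np.empty(len(df), dtype=float)
    cols = {name: df[col].to_numpy(dtype=float) for name, col in PANEL_COLUMNS.items()}
    ages = df["age_years"].to_numpy(dtype=float)
    for i in range(len(df)):
        panel = validate_panel(BiomarkerPanel(**{n: cols[n][i] for n in BIOMARKERS}))
        out[i] = compute_phenoage(panel, ages[i], coeffs).phenoage
    return out
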