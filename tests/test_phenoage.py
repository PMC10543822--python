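"""The clock transform chain: validation, linear predictor, Gompertz risk,
age-scale inversion, and equivalence with a direct evaluation oracle."""

import math
from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

from phenoaccel.phenoage import (
    BIOMARKERS,
    BiomarkerPanel,
    PanelValidationError,
    compute_phenoage,
    convert_to_canonical,
    linear_predictor,
    load_coefficients,
    mortality_risk,
    phenoage_from_risk,
    score_dataframe,
    validate_panel,
)
from conftest import random_panel


def risk_from_phenoage(pheno, coeffs):
    """Algebraic inverse of the age-scale transform (test-only)."""
    return 1.0 - math.exp(math.exp((pheno - coeffs.inv_c) * coeffs.inv_b) / coeffs.inv_a)


class TestValidation:
    def test_crp_zero_clamped_to_floor(self, reference_panel):
        panel = replace(reference_panel, crp=0.0)
        assert validate_panel(panel).crp == pytest.approx(0.01)

    def test_valid_panel_unchanged(self, reference_panel):
        assert validate_panel(reference_panel) == reference_panel

    @pytest.mark.parametrize("field,value", [
        ("lymphocyte_pct", 150.0),
        ("albumin", -3.0),
        ("wbc", float("nan")),
        ("mcv", float("inf")),
        ("crp", -1.0),
    ])
    def test_out_of_range_error_names_analyte(self, reference_panel, field, value):
        panel = replace(reference_panel, **{field: value})
        with pytest.raises(PanelValidationError, match=field):
            validate_panel(panel)


class TestLinearPredictor:
    def test_reference_panel_golden_value(self, reference_panel, coeffs):
        xb = linear_predictor(reference_panel, 60.0, coeffs)
        assert xb == pytest.approx(-8.040966617871629, abs=1e-9)

    def test_age_shift_is_exactly_age_weight(self, reference_panel, coeffs):
        a = linear_predictor(reference_panel, 60.0, coeffs)
        b = linear_predictor(reference_panel, 61.0, coeffs)
        assert b - a == pytest.approx(coeffs.age_weight, abs=1e-12)

    def test_doubling_a_weight_doubles_its_contribution(self, reference_panel, coeffs):
        doubled = replace(coeffs, weights={**coeffs.weights, "rdw": 2 * coeffs.weights["rdw"]})
        diff = linear_predictor(reference_panel, 60.0, doubled) - linear_predictor(
            reference_panel, 60.0, coeffs
        )
        assert diff == pytest.approx(coeffs.weights["rdw"] * reference_panel.rdw, rel=1e-12)


class TestMortalityRisk:
    def test_reference_golden_value(self, coeffs):
        assert mortality_risk(-8.040966617871629, coeffs) == pytest.approx(
            0.061529473759937, abs=1e-9
        )

    def test_extreme_negative_xb_hits_lower_clamp(self, coeffs):
        assert mortality_risk(-1e6, coeffs) == pytest.approx(1e-12)

    def test_extreme_positive_xb_hits_upper_clamp(self, coeffs):
        assert mortality_risk(1e6, coeffs) == pytest.approx(1 - 1e-12)

    def test_strictly_increasing_in_xb(self, coeffs):
        # below xb ~ -1.7 the risk saturates to the upper clamp in float64,
        # so monotonicity is checked over the informative range
        grid = np.linspace(-30, -4, 1000)
        risks = [mortality_risk(x, coeffs) for x in grid]
        assert np.all(np.diff(risks) > 0)


class TestAgeScaleInverse:
    def test_reference_golden_value(self, coeffs):
        m = mortality_risk(-8.040966617871629, coeffs)
        assert phenoage_from_risk(m, coeffs) == pytest.approx(54.713133305966, abs=1e-6)

    def test_inner_product_one_gives_inv_c(self, coeffs):
        # choose m so that inv_a * ln(1-m) = 1; with the default inv_a that
        # m is unrepresentably close to 1, so use a milder inv_a
        mild = replace(coeffs, inv_a=-0.5)
        m = 1.0 - math.exp(1.0 / mild.inv_a)
        assert phenoage_from_risk(m, mild) == pytest.approx(mild.inv_c, abs=1e-12)

    @pytest.mark.parametrize("m", [0.0, 1.0, -0.1, 1.5])
    def test_out_of_domain_risk_rejected(self, coeffs, m):
        with pytest.raises(ValueError):
            phenoage_from_risk(m, coeffs)

    def test_round_trip_with_algebraic_inverse(self, coeffs):
        for m in np.linspace(0.001, 0.999, 200):
            assert risk_from_phenoage(phenoage_from_risk(m, coeffs), coeffs) == pytest.approx(
                m, abs=1e-9
            )


class TestComputePhenoage:
    def test_reference_golden_triplet(self, reference_panel, coeffs):
        r = compute_phenoage(reference_panel, 60.0, coeffs)
        assert r.xb == pytest.approx(-8.040966617871629, abs=1e-9)
        assert r.mortality_risk == pytest.approx(0.061529473759937, abs=1e-9)
        assert r.phenoage == pytest.approx(54.713133305966, abs=1e-6)

    def test_matches_direct_evaluation_oracle_on_random_panels(
        self, coeffs, raw_constants, phenoage_oracle
    ):
        rng = np.random.default_rng(20240901)
        for _ in range(50):
            panel = random_panel(rng)
            age = rng.uniform(18, 95)
            r = compute_phenoage(validate_panel(panel), age, coeffs)
            _, _, expected = phenoage_oracle(panel.as_dict(), age, raw_constants)
            assert r.phenoage == pytest.approx(expected, abs=1e-9)

    def test_monotone_in_each_biomarker_matches_weight_sign(self, coeffs):
        rng = np.random.default_rng(42)
        checked = 0
        while checked < 100:
            panel = random_panel(rng)
            age = rng.uniform(18, 90)
            base = compute_phenoage(validate_panel(panel), age, coeffs)
            if base.mortality_risk > 1 - 1e-9:
                continue  # clamped region: derivative is zero by design
            name = BIOMARKERS[rng.integers(len(BIOMARKERS))]
            bumped = replace(panel, **{name: getattr(panel, name) * 1.01})
            new = compute_phenoage(validate_panel(bumped), age, coeffs)
            assert np.sign(new.phenoage - base.phenoage) == np.sign(coeffs.weights[name])
            checked += 1

    def test_deterministic(self, reference_panel, coeffs):
        a = compute_phenoage(reference_panel, 60.0, coeffs)
        b = compute_phenoage(reference_panel, 60.0, coeffs)
        assert a == b

    def test_coefficient_injection_changes_results(self, reference_panel, coeffs, tmp_path):
        import json
        from importlib import resources

        raw = json.loads(
            (resources.files("phenoaccel.constants") / "phenoage_levine_default.json").read_text()
        )
        raw["age_weight"] = 0.1
        alt_path = tmp_path / "alt.json"
        alt_path.write_text(json.dumps(raw))
        alt = load_coefficients(str(alt_path))
        r_default = compute_phenoage(reference_panel, 60.0, coeffs)
        r_alt = compute_phenoage(reference_panel, 60.0, alt)
        assert r_alt.xb == pytest.approx(r_default.xb + (0.1 - coeffs.age_weight) * 60.0)


class TestUnitsAndVectorised:
    @pytest.mark.parametrize("analyte,value,unit,expected", [
        ("crp", 10.0, "mg/L", 1.0),
        ("glucose", 90.08, "mg/dL", 5.0),
        ("wbc", 7.0, "10^9/L", 7.0),
        ("albumin", 4.0, "g/dL", 40.0),
    ])
    def test_unit_dialect_conversion(self, analyte, value, unit, expected):
        assert convert_to_canonical(analyte, value, unit) == pytest.approx(expected, rel=1e-3)

    def test_unknown_unit_rejected(self):
        with pytest.raises(PanelValidationError):
            convert_to_canonical("crp", 1.0, "furlongs")

    def test_score_dataframe_matches_scalar_path(self, reference_panel, coeffs):
        df = pd.DataFrame([{
            "albumin_g_l": 40.0, "creatinine_umol_l": 80.0, "glucose_mmol_l": 5.0,
            "crp_mg_dl": 0.1, "lymphocyte_pct": 30.0, "mcv_fl": 90.0, "rdw_pct": 13.0,
            "alp_u_l": 70.0, "wbc_10e9_l": 7.0, "age_years": 60.0,
        }])
        out = score_dataframe(df, coeffs)
        assert out[0] == pytest.approx(
            compute_phenoage(reference_panel, 60.0, coeffs).phenoage, abs=1e-12
        )
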