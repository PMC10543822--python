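import json
import math
from importlib import resources

import numpy as np
import pytest

from phenoaccel.phenoage import BiomarkerPanel, load_coefficients


@pytest.fixture(scope="session")
def coeffs():
    return load_coefficients()


@pytest.fixture(scope="session")
def raw_constants():
    ref = resources.files("phenoaccel.constants") / "phenoage_levine_default.json"
    return json.loads(ref.read_text())


@pytest.fixture
def reference_panel():
    """A biochemically unremarkable adult panel in canonical units."""
    return BiomarkerPanel(
        albumin=40.0, creatinine=80.0, glucose=5.0, crp=0.1,
        lymphocyte_pct=30.0, mcv=90.0, rdw=13.0, alp=70.0, wbc=7.0,
    )


def oracle_phenoage(values: dict, age: float, constants: dict) -> tuple[float, float, float]:
    """Independent direct evaluation of the clock equations from the raw
    constants file, bypassing the package's transform chain. Applies the
    same documented two-sided risk clamp (1e-12) so the age-scale inverse
    is defined for extreme panels."""
    xb = constants["intercept"] + constants["age_weight"] * age
    for name, w in constants["weights"].items():
        v = values[name]
        xb += w * (math.log(v) if name == "crp" else v)
    g = constants["gompertz_gamma"]
    m = 1.0 - math.exp(-math.exp(xb) * (math.exp(g * constants["horizon_months"]) - 1.0) / g)
    m = min(max(m, 1e-12), 1.0 - 1e-12)
    pheno = constants["inv_c"] + math.log(constants["inv_a"] * math.log(1.0 - m)) / constants["inv_b"]
    return xb, m, pheno


@pytest.fixture(scope="session")
def phenoage_oracle():
    return oracle_phenoage


def random_panel(rng: np.random.Generator) -> BiomarkerPanel:
    """A random physiologically plausible canonical-unit panel; a shared
    severity factor correlates the markers the way acute illness does."""
    z = rng.normal()
    return BiomarkerPanel(
        albumin=float(np.clip(rng.normal(40 - 2 * z, 4), 15, 55)),
        creatinine=float(np.clip(rng.normal(85 + 20 * z, 25), 30, 600)),
        glucose=float(np.clip(rng.normal(7 + 0.8 * z, 1.8), 2.5, 25)),
        crp=float(np.clip(np.exp(rng.normal(np.log(5) + 0.35 * z, 1.1)), 0.005, 50)),
        lymphocyte_pct=float(np.clip(rng.normal(18 - 2 * z, 7), 1, 60)),
        mcv=float(np.clip(rng.normal(90 + 1.5 * z, 4.5), 65, 125)),
        rdw=float(np.clip(rng.normal(14 + 1.2 * z, 1.6), 11.5, 25)),
        alp=float(np.clip(np.exp(rng.normal(np.log(85) + 0.12 * z, 0.45)), 20, 900)),
        wbc=float(np.clip(rng.normal(11 + 1.2 * z, 4), 0.6, 60)),
    )
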