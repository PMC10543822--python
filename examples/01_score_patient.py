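"""Score a single patient's blood panel with the PhenoAge clock.

Builds a biochemically unremarkable 60-year-old's panel in canonical units
and walks it through the transform chain: linear predictor -> Gompertz
10-year mortality risk -> phenotypic age in years.
"""

from phenoaccel import BiomarkerPanel, compute_phenoage, validate_panel

panel = validate_panel(BiomarkerPanel(
    albumin=40.0,          # g/L
    creatinine=80.0,       # umol/L
    glucose=5.0,           # mmol/L
    crp=0.1,               # mg/dL (enters as ln CRP)
    lymphocyte_pct=30.0,   # % of WBC
    mcv=90.0,              # fL
    rdw=13.0,              # %
    alp=70.0,              # U/L
    wbc=7.0,               # 10^9/L
))

result = compute_phenoage(panel, age=60.0)
print(f"linear predictor xb : {result.xb:.4f}")
print(f"10-y mortality risk : {result.mortality_risk:.4f}")
print(f"PhenoAge            : {result.phenoage:.2f} years")
print()
print("A PhenoAge below the chronological 60 y means this panel looks"
      " biologically younger than the calendar age; each biomarker shifts"
      " the linear predictor by its weight, and the Gompertz transform maps"
      " it onto the age scale.")
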