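{
    "name": "phenoage_levine_default",
    "intercept": -19.907,
    "weights": {
        "albumin": -0.0336,
        "creatinine": 0.0095,
        "glucose": 0.1953,
        "crp": 0.0954,
        "lymphocyte_pct": -0.012,
        "mcv": 0.0268,
        "rdw": 0.3306,
        "alp": 0.00188,
        "wbc": 0.0554
    },
    "age_weight": 0.0804,
    "gompertz_gamma": 0.0076927,
    "horizon_months": 120.0,
    "inv_a": -0.00553,
    "inv_b": 0.09165,
    "inv_c": 141.50225
}
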