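{
  "name": "us3l_synthetic",
  "description": "Synthetic stand-in value set with the structure of the published US EQ-5D-3L valuation (additive per-dimension level-2/3 decrements, an any-dysfunction constant shift, and an extra decrement per level-3 dimension beyond the first). Calibrated so full health scores 1.0, the worst state 33333 scores -0.108, and common mild states fall near 0.8. It is NOT the published US tariff; load a transcribed value-set JSON for production scoring.",
  "decrements": {
    "mobility": {"2": -0.070, "3": -0.180},
    "self_care": {"2": -0.085, "3": -0.190},
    "usual_activities": {"2": -0.065, "3": -0.160},
    "pain_discomfort": {"2": -0.075, "3": -0.200},
    "anxiety_depression": {"2": -0.070, "3": -0.180}
  },
  "extra_terms": [
    {"name": "D1", "feature": "any_dysfunction", "coefficient": -0.110, "power": 1},
    {"name": "I3", "feature": "count_level3_minus_1", "coefficient": -0.022, "power": 1}
  ]
}
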