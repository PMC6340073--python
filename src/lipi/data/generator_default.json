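{
  "n_patients": 55,
  "dist_specs": [
    {"feature": "th17", "median": 4.0, "q1": 2.0, "q3": 10.5, "family": "lognormal"},
    {"feature": "b_cells", "median": 163.5, "q1": 55.75, "q3": 352.25, "family": "lognormal"},
    {"feature": "tlr2_mfi", "median": 9567.0, "q1": 5552.0, "q3": 13848.0, "family": "lognormal"},
    {"feature": "ldg", "median": 43.0, "q1": 19.0, "q3": 110.0, "family": "lognormal"},
    {"feature": "lymphocytes", "median": 1084.0, "q1": 686.0, "q3": 1659.0, "family": "lognormal"}
  ],
  "outcome": {
    "effects": {"th17": 2.0, "b_cells": -2.0, "tlr2_mfi": -1.0},
    "binary_effects": {"cyclophosphamide": 1.5},
    "target_prevalence": 0.327
  },
  "visit_days": [0, 30, 90, 180],
  "cyc_fraction": 0.109,
  "icc": 0.5,
  "followup_days": 365,
  "seed": 0
}
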