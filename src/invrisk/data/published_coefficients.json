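{
  "version": 1,
  "description": "Published logistic-regression coefficients (logit scale) for the three supported invasion-risk submodels.",
  "host_evolution": {
    "folivore": {
      "intercept": -0.515,
      "log10_divergence": 8.073,
      "log10_divergence_sq": -9.495,
      "se": {"intercept": 1.120, "log10_divergence": 5.086, "log10_divergence_sq": 5.271},
      "n": 49
    },
    "sap_feeder": {
      "intercept": -51.824,
      "log10_divergence": 84.472,
      "log10_divergence_sq": -35.803,
      "se": {"intercept": 21.149, "log10_divergence": 34.739, "log10_divergence_sq": 14.182},
      "n": 131
    }
  },
  "host_traits": {
    "intercept": -3.656,
    "shade_tolerance": {"reference": "low", "moderate": 0.634, "high": 2.434},
    "drought_tolerance": {"reference": "none", "low": -0.108, "moderate": 0.171, "high": -0.582},
    "se": {
      "intercept": 1.423,
      "shade_tolerance.moderate": 1.013,
      "shade_tolerance.high": 0.816,
      "drought_tolerance.low": 1.297,
      "drought_tolerance.moderate": 1.354,
      "drought_tolerance.high": 1.504
    },
    "n": 221
  },
  "insect_evolution": {
    "intercept": -2.180,
    "shared_genus": -2.124,
    "se": {"intercept": 0.293, "shared_genus": 1.048},
    "n": 203
  },
  "overall_baseline": 0.072
}
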