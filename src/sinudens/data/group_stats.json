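{
  "description": "Per-group means and standard deviations of the five diagnostic indicators for the clinical cohorts (conditional norm and four forms of odontogenic sinusitis), with the published normalized Euclidean distances and decision-error probabilities for the eight tabulated group comparisons.",
  "indicators": {
    "x1": "density of the fluid content of the sinus, Hu",
    "x2": "relative opening area of the anastomosis, %",
    "x3": "relative volume of the sinus mucosa, %",
    "x4": "relative volume of the fluid content of the sinus, %",
    "x5": "aerodynamic nasal drag coefficient A, kPa/(L/s)"
  },
  "groups": {
    "conditional_norm": {
      "n": 38,
      "mean": {"x1": -630, "x2": 96, "x3": 10, "x4": 0, "x5": 0.45},
      "sd":   {"x1": 330,  "x2": 39, "x3": 5.7, "x4": 0, "x5": 0.24}
    },
    "acute_serous": {
      "n": 35,
      "mean": {"x1": 19, "x2": 24, "x3": 16.2, "x4": 52, "x5": 1.58},
      "sd":   {"x1": 4.3, "x2": 12, "x3": 14.5, "x4": 30.5, "x5": 0.87}
    },
    "acute_purulent": {
      "n": 36,
      "mean": {"x1": 37, "x2": 20, "x3": 27, "x4": 54.3, "x5": 2.2},
      "sd":   {"x1": 6.2, "x2": 9, "x3": 16, "x4": 32, "x5": 1.12}
    },
    "chronic": {
      "n": 38,
      "mean": {"x1": 39, "x2": 64, "x3": 62, "x4": 15, "x5": 1.72},
      "sd":   {"x1": 6.4, "x2": 25.5, "x3": 25, "x4": 9, "x5": 1.12}
    },
    "exacerbated_chronic": {
      "n": 32,
      "mean": {"x1": 38.5, "x2": 23, "x3": 65, "x4": 28, "x5": 1.94},
      "sd":   {"x1": 6.1, "x2": 11.2, "x3": 31, "x4": 12, "x5": 1.28}
    }
  },
  "comparisons": [
    {"pair": ["conditional_norm", "acute_serous"], "printed_delta": 3.34, "printed_per": 0.1},
    {"pair": ["conditional_norm", "acute_purulent"], "printed_delta": 3.78, "printed_per": 0.06},
    {"pair": ["conditional_norm", "chronic"], "printed_delta": 3.16, "printed_per": 0.12},
    {"pair": ["conditional_norm", "exacerbated_chronic"], "printed_delta": 4.29, "printed_per": 0.04},
    {"pair": ["acute_serous", "acute_purulent"], "printed_delta": 3.36, "printed_per": 0.09},
    {"pair": ["chronic", "acute_purulent"], "printed_delta": 2.18, "printed_per": 0.31},
    {"pair": ["acute_purulent", "exacerbated_chronic"], "printed_delta": 1.71, "printed_per": 0.4},
    {"pair": ["chronic", "exacerbated_chronic"], "printed_delta": 1.98, "printed_per": 0.32}
  ]
}
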