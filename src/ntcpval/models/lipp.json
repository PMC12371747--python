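{
  "intercept": -2.2951,
  "coef_parotid": 0.0996,
  "coef_smg": 0.0182,
  "baseline_scores": {
    "none": 0.0,
    "mild": 0.459,
    "moderate_severe": 1.207
  },
  "dose_transform": "identity",
  "provenance": "LIPP xerostomia grade >= 2 at 6 months, published coefficients"
}
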