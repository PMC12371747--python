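{
  "intercept": -3.2132,
  "coef_parotid": 0.1354,
  "coef_smg": 0.0247,
  "baseline_scores": {
    "none": 0.0,
    "mild": 0.624,
    "moderate_severe": 1.641
  },
  "dose_transform": "identity",
  "provenance": "LIPP model recalibrated on the external validation cohort (published); baseline scores scaled by the fitted slope 1.36"
}
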