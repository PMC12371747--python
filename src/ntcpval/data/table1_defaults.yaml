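# Default study conditions for the synthetic registry generator.
# Dose targets are the published per-gland median physical mean doses (Gy)
# with quartiles; the remaining settings mirror the cohort description
# (follow-up 5-24 months with median 10.3, ~15% baseline recording with
# 83/16/1% none/mild/moderate-severe, exclusion-flag counts 61/34/71).
n: 674
seed: 0
dose_targets:
  parotid_ipsi: [28.3, 22.4, 37.9]
  parotid_contra: [16.2, 11.0, 19.6]
  smg_ipsi: [65.2, 59.0, 67.6]
  smg_contra: [46.2, 39.6, 51.7]
rho: 0.4
dose_bounds: [0.5, 80.0]
baseline_recorded_fraction: 0.15
baseline_probs: [0.83, 0.16, 0.01]
delta_a: 0.0
delta_b: 1.0
followup_window: [5.0, 24.0]
followup_median: 10.3
exclusion_counts:
  plan_adaptation: 61
  brachy_boost: 34
  reirradiation: 71
dose_representation: eqd2
smg_combination: combined
alpha_beta: 3.0
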