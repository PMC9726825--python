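# Warm-temperature reference: fast transcription (58,000 mRNA/h, 20 min
# half-life) and rapid induction; cell-cycle phases in hours.
name: wildtype_30C
temperature_C: 30.0
ros_mu_log: 4.605170185988092  # ln(100): low ROS at optimal temperature
ros_sigma_log: 0.8
ros_threshold: 6000.0
phase_means_h: {g1: 0.5, s: 0.5, g2: 0.2, m: 0.4}
phase_cv: 0.2
non_divider_fraction: 0.0
horizon_days: 2.0
cadence_per_day: 96.0
growth_rate_au_per_h: 10.0
g_per_day: 8.0
d_per_day: 0.1
density_threshold: 1.0
k_syn_per_h: 58000.0
mrna_half_life_h: 0.3333333333333333  # 20 min
induction_A_au: 100.0
induction_k_per_h: 1.0
induction_t0_h: 1.0
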