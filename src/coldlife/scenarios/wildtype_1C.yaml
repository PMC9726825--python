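# Wild-type cells at 1 degC: replicative (S-G2-M) phase totals 28.4 days
# (split in the same 25:6:22 proportions as at 5 degC); movies span 51 days.
name: wildtype_1C
temperature_C: 1.0
ros_mu_log: 8.294049640102028  # ln(4000)
ros_sigma_log: 1.0
ros_threshold: 6000.0
phase_means_h: {g1: 72.0, s: 321.5, g2: 77.2, m: 282.9}  # S-G2-M = 681.6 h
phase_cv: 0.2
non_divider_fraction: 0.3
horizon_days: 51.0
growth_rate_au_per_h: 0.05
g_per_day: 0.006
d_per_day: 0.03
density_threshold: 1.0e+9  # no density grows at 1 degC
k_syn_per_h: 700.0
mrna_half_life_h: 14.0
induction_A_au: 100.0
induction_k_per_h: 0.005
induction_t0_h: 36.0
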