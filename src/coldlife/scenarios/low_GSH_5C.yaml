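# Growing high-density population at 5 degC with little ambient antioxidant:
# high median ROS, long G1 (32 h mean among dividers), 28-day lifespan growth.
name: low_GSH_5C
temperature_C: 5.0
ros_mu_log: 7.600902459542082  # ln(2000): median 2000 arb. units
ros_sigma_log: 1.0
ros_threshold: 6000.0
phase_means_h: {g1: 32.0, s: 25.0, g2: 6.0, m: 22.0}
phase_cv: 0.2
non_divider_fraction: 0.2
horizon_days: 30.0
growth_rate_au_per_h: 0.149  # (120 - 20) au over a 28-day life
g_per_day: 0.12
d_per_day: 0.04
density_threshold: 3000.0
k_syn_per_h: 2000.0
mrna_half_life_h: 7.0
induction_A_au: 100.0
induction_k_per_h: 0.02
induction_t0_h: 12.0
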