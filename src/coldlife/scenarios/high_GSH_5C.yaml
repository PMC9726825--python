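# Low-density population grown with 250 uM glutathione at 5 degC: ~10-fold
# lower median ROS, short G1 (14.7 h mean), faster size growth.
name: high_GSH_5C
temperature_C: 5.0
ros_mu_log: 5.298317366548036  # ln(200): 10-fold below the low-GSH median
ros_sigma_log: 1.0
ros_threshold: 6000.0
phase_means_h: {g1: 14.7, s: 25.0, g2: 6.0, m: 22.0}
phase_cv: 0.2
non_divider_fraction: 0.05
horizon_days: 30.0
growth_rate_au_per_h: 0.25
g_per_day: 0.18
d_per_day: 0.03
density_threshold: 250.0
k_syn_per_h: 2000.0
mrna_half_life_h: 7.0
induction_A_au: 100.0
induction_k_per_h: 0.02
induction_t0_h: 12.0
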