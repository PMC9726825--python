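# Knockout of the glutathione-dependent ROS-reducing enzymes at 5 degC:
# ROS near the division threshold, population doubling stretched to 35 days.
name: grx2_gtt2_KO_5C
temperature_C: 5.0
ros_mu_log: 8.517193191416238  # ln(5000): just under the 6000 threshold
ros_sigma_log: 1.0
ros_threshold: 6000.0
phase_means_h: {g1: 60.0, s: 25.0, g2: 6.0, m: 22.0}
phase_cv: 0.2
non_divider_fraction: 0.5
horizon_days: 60.0
growth_rate_au_per_h: 0.12
g_per_day: 0.0398
d_per_day: 0.02  # net 0.0198/day: doubling every 35 days
density_threshold: 3000.0
k_syn_per_h: 2000.0
mrna_half_life_h: 7.0
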