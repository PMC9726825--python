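# Medium with non-sugar nutrients cut by 80% (glucose unchanged): the
# medium oxidation rate drops by ~85% relative to the 1x control.
name: dilute_medium_0.2x
temperature_C: 5.0
ros_mu_log: 6.396929655216146  # ln(600)
ros_sigma_log: 1.0
oxidation_fold: 0.15
g_per_day: 0.2
d_per_day: 0.0267  # net 0.1733/day: doubling every 4 days
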