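# Growth medium with the superoxide scavenger Trolox: sixfold lower
# medium oxidation rate than the untreated 1x medium at 5 degC.
name: trolox_medium
temperature_C: 5.0
ros_mu_log: 6.214608098422191  # ln(500)
ros_sigma_log: 1.0
oxidation_fold: 0.16666666666666666
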