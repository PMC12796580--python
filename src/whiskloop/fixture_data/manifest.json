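{
  "fixtures": [
    "psth_worked_example",
    "psth_single_spike_per_sweep",
    "interneuron_boundary",
    "interneuron_criteria",
    "layer_table",
    "anova_2x2_hand",
    "onset_step",
    "bonferroni_cases",
    "condition_delta",
    "slope_ramp",
    "rout_single_contaminant",
    "optotag_cases"
  ]
}
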