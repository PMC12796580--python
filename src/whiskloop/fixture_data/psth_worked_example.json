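{
  "name": "psth_worked_example",
  "provenance": "reported",
  "oracle": "printed worked example of the per-sweep normalization convention",
  "inputs": {"total_spikes": 100, "n_sweeps": 30, "window_s": 1.0},
  "expected": {"window_rate_spikes_per_s": 3.3333333333333335, "printed": 3.33}
}
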