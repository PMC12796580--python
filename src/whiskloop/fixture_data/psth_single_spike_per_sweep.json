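{
  "name": "psth_single_spike_per_sweep",
  "provenance": "forced",
  "oracle": "forced by the normalization formula count/n_sweeps/bin_width_s",
  "inputs": {
    "spike_offset_ms": 10.0,
    "n_sweeps": 30,
    "bin_width_ms": 2.0,
    "window_ms": [0.0, 20.0]
  },
  "expected": {"bin_start_ms": 10.0, "bin_rate_spikes_per_s": 500.0, "other_bins": 0.0}
}
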