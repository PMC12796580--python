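{
  "name": "slope_ramp",
  "provenance": "forced",
  "oracle": "exact line: OLS on collinear points returns the line's slope",
  "inputs": {
    "ramp_start_ms": 0.0,
    "ramp_end_ms": 20.0,
    "rate_start": 0.0,
    "rate_end": 40.0,
    "bin_width_ms": 2.0
  },
  "expected": {"slope_spikes_per_s_per_ms": 2.0}
}
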