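{
  "name": "onset_step",
  "provenance": "forced",
  "oracle": "forced by the consecutive-bins rule: baseline SD is 0, so the threshold equals the baseline mean and the step starting at +6 ms opens a run of 10 supra-threshold bins",
  "inputs": {
    "baseline_rate": 5.0,
    "baseline_window_ms": 200.0,
    "step_rate": 20.0,
    "step_onset_ms": 6.0,
    "step_bins": 10,
    "bin_width_ms": 2.0,
    "post_window_ms": 100.0
  },
  "expected": {"onset_ms": 6.0}
}
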