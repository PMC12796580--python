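{
  "name": "condition_delta",
  "provenance": "reported",
  "oracle": "subtraction of the reported POm non-whisking spontaneous rates with and without photoinactivation",
  "inputs": {"control_rate": 7.09, "opto_rate": 3.79},
  "expected": {"delta_rate": 3.30}
}
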