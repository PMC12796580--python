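{
  "name": "interneuron_boundary",
  "provenance": "reported",
  "oracle": "strict inequalities of the three-feature interneuron rule",
  "inputs": {"peak_amplitude_asymmetry": 0.15, "trough_to_peak": 0.25, "half_width": 0.15},
  "expected": {"interneuron": false}
}
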