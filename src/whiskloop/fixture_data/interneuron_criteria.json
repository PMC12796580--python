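{
  "name": "interneuron_criteria",
  "provenance": "reported",
  "oracle": "conjunction of asymmetry > 0.15, trough-to-peak < 0.3 ms, half-width < 0.2 ms",
  "inputs": {
    "cases": [
      {"features": [0.20, 0.25, 0.15], "interneuron": true},
      {"features": [0.20, 0.35, 0.15], "interneuron": false},
      {"features": [0.20, 0.30, 0.15], "interneuron": false},
      {"features": [0.10, 0.25, 0.15], "interneuron": false},
      {"features": [0.20, 0.25, 0.20], "interneuron": false}
    ]
  },
  "expected": {}
}
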