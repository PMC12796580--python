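{
  "name": "bonferroni_cases",
  "provenance": "forced",
  "oracle": "forced arithmetic: p -> min(1, p*m)",
  "inputs": {
    "cases": [
      {"p": 0.02, "m": 2, "adjusted": 0.04},
      {"p": 0.8, "m": 3, "adjusted": 1.0},
      {"p": 0.3, "m": 1, "adjusted": 0.3}
    ]
  },
  "expected": {}
}
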