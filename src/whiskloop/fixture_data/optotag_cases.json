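{
  "name": "optotag_cases",
  "provenance": "derived",
  "oracle": "direct evaluation of the tagging criterion on analytic (noise-free) PSTHs: a 0.5 spikes/s baseline falls below the 1 spike/s floor; a 5 spikes/s unit fully silenced at 2 ms latency has a zero tag-window rate which satisfies the mu - 2*sigma bound (sigma = 0); an unmodulated unit keeps its baseline rate, which does not",
  "inputs": {
    "cases": [
      {"baseline_rate": 0.5, "tag_window_rate": 0.0, "pulse_rate": 0.0,
       "expected": "unclassifiable"},
      {"baseline_rate": 5.0, "tag_window_rate": 0.0, "pulse_rate": 0.0,
       "expected": "tagged"},
      {"baseline_rate": 5.0, "tag_window_rate": 5.0, "pulse_rate": 5.0,
       "expected": "not_tagged"}
    ]
  },
  "expected": {}
}
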