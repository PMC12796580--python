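{
  "name": "rout_single_contaminant",
  "provenance": "derived",
  "oracle": "direct evaluation of the sequential FDR test: the contaminant's standardized residual is ~100 robust SDs (p ~ 0) while the largest clean deviate is ~2.5 SDs (p ~ 0.018 > Q*2/31), so exactly the last value is flagged; the 30 clean values are frozen draws from a standard normal (generator seed 7)",
  "inputs": {
    "values": [0.0012, 0.2987, -0.2741, -0.8906, -0.4547, -0.9916, 0.0601, 1.3402,
               -0.4922, -0.6205, 0.4898, 0.3569, 0.1054, -0.9305, -0.0293, 0.6953,
               -1.3442, -0.4576, -1.9012, -1.2895, -1.8417, -0.2351, -1.2674, 0.2713,
               0.1568, -0.1869, -2.5168, -0.5387, -0.0485, 0.1133, 100.0],
    "q_percent": 1.0
  },
  "expected": {"outlier_indices": [30]}
}
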