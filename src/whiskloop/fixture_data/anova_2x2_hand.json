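{
  "name": "anova_2x2_hand",
  "provenance": "derived",
  "oracle": "manual sums-of-squares arithmetic in exact rational form: grand mean 91/16; SS_A = n*b*sum((m_a-g)^2) = 225/4, SS_B = n*a*sum((m_b-g)^2) = 36, SS_AB = n*sum((m_ab-m_a-m_b+g)^2) = 1; error terms SS_AxS = 5/4, SS_BxS = 1/2, SS_AxBxS = 1/2; F = (SS_eff/df_eff)/(SS_err/df_err) with df_err = 3",
  "inputs": {
    "subjects": ["s1", "s2", "s3", "s4"],
    "row_levels": ["a1", "a2"],
    "col_levels": ["b1", "b2"],
    "values": {
      "s1": [[3, 5], [6, 10]],
      "s2": [[2, 4], [5, 8]],
      "s3": [[4, 7], [8, 12]],
      "s4": [[3, 6], [6, 9]]
    }
  },
  "expected": {
    "SS_total": 113.75,
    "SS_subject": 18.25,
    "SS_row": 56.25,
    "SS_col": 36.0,
    "SS_interaction": 1.0,
    "SS_row_x_subject": 1.25,
    "SS_col_x_subject": 0.5,
    "SS_residual": 0.5,
    "F_row": 135.0,
    "F_col": 216.0,
    "F_interaction": 6.0,
    "df": [1, 3],
    "p_row": 0.0013693312368810763,
    "p_col": 0.000683280220568194,
    "p_interaction": 0.09172111331157186
  }
}
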