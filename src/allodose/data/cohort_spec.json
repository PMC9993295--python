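{
 "seed": 42,
 "sex_ratio_male": 0.449438202247191,
 "strata": [
  {"age_years": 2, "n": 4, "mean_kg": 12.0, "min_kg": 9.6, "max_kg": 14.5},
  {"age_years": 3, "n": 4, "mean_kg": 13.4, "min_kg": 12.3, "max_kg": 14.9},
  {"age_years": 4, "n": 2, "mean_kg": 12.9, "min_kg": 11.7, "max_kg": 14.2},
  {"age_years": 5, "n": 3, "mean_kg": 16.5, "min_kg": 14.3, "max_kg": 17.6},
  {"age_years": 6, "n": 4, "mean_kg": 18.8, "min_kg": 15.1, "max_kg": 23.1},
  {"age_years": 7, "n": 9, "mean_kg": 19.8, "min_kg": 15.0, "max_kg": 29.0},
  {"age_years": 8, "n": 11, "mean_kg": 24.0, "min_kg": 18.1, "max_kg": 31.3},
  {"age_years": 9, "n": 9, "mean_kg": 23.5, "min_kg": 19.8, "max_kg": 28.2},
  {"age_years": 10, "n": 11, "mean_kg": 28.3, "min_kg": 22.3, "max_kg": 41.5},
  {"age_years": 11, "n": 15, "mean_kg": 29.4, "min_kg": 21.8, "max_kg": 35.0},
  {"age_years": 12, "n": 17, "mean_kg": 31.9, "min_kg": 23.7, "max_kg": 58.8}
 ]
}
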