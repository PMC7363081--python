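{
  "adult": [
    {"temperature_C": 13.5, "n_female": 17, "female_longevity_mean": 94.1, "female_longevity_se": 10.72, "female_longevity_median": 87.0, "fecundity_mean": null, "fecundity_se": null, "n_male": 24, "male_longevity_mean": 113.0, "male_longevity_se": 5.68, "male_longevity_median": 122.3},
    {"temperature_C": 16.7, "n_female": 20, "female_longevity_mean": 53.5, "female_longevity_se": 4.46, "female_longevity_median": 54.5, "fecundity_mean": 63.0, "fecundity_se": 22.5, "n_male": 21, "male_longevity_mean": 51.4, "male_longevity_se": 3.25, "male_longevity_median": 53.8},
    {"temperature_C": 18.8, "n_female": 18, "female_longevity_mean": 116.8, "female_longevity_se": 7.45, "female_longevity_median": 107.0, "fecundity_mean": 922.0, "fecundity_se": 86.7, "n_male": 29, "male_longevity_mean": 79.6, "male_longevity_se": 6.35, "male_longevity_median": 76.5},
    {"temperature_C": 23.5, "n_female": 20, "female_longevity_mean": 78.5, "female_longevity_se": 6.4, "female_longevity_median": 71.0, "fecundity_mean": 1545.0, "fecundity_se": 160.6, "n_male": 36, "male_longevity_mean": 68.1, "male_longevity_se": 4.03, "male_longevity_median": 62.0},
    {"temperature_C": 28.1, "n_female": 16, "female_longevity_mean": 43.3, "female_longevity_se": 4.33, "female_longevity_median": 39.0, "fecundity_mean": 1684.0, "fecundity_se": 131.9, "n_male": 30, "male_longevity_mean": 43.3, "male_longevity_se": 2.08, "male_longevity_median": 44.0},
    {"temperature_C": 32.0, "n_female": 17, "female_longevity_mean": 42.1, "female_longevity_se": 4.63, "female_longevity_median": 37.8, "fecundity_mean": 958.0, "fecundity_se": 86.9, "n_male": 33, "male_longevity_mean": 30.9, "male_longevity_se": 1.79, "male_longevity_median": 28.8},
    {"temperature_C": 34.9, "n_female": 17, "female_longevity_mean": 22.4, "female_longevity_se": 1.81, "female_longevity_median": 21.5, "fecundity_mean": 138.0, "fecundity_se": 34.2, "n_male": 34, "male_longevity_mean": 19.0, "male_longevity_se": 0.59, "male_longevity_median": 19.0}
  ],
  "oviposition": [
    {"temperature_C": 16.7, "n_ovipositing": 11, "apop_mean": 38.1, "apop_se": 3.06, "aop_mean": 23.6, "aop_se": 4.27, "tpop_mean": 91.2},
    {"temperature_C": 18.8, "n_ovipositing": 17, "apop_mean": 16.2, "apop_se": 0.75, "aop_mean": 103.1, "aop_se": 7.2, "tpop_mean": 49.1},
    {"temperature_C": 23.5, "n_ovipositing": 20, "apop_mean": 9.0, "apop_se": 0.21, "aop_mean": 69.5, "aop_se": 6.46, "tpop_mean": 31.1},
    {"temperature_C": 28.1, "n_ovipositing": 16, "apop_mean": 5.4, "apop_se": 0.58, "aop_mean": 37.8, "aop_se": 4.24, "tpop_mean": 24.1},
    {"temperature_C": 32.0, "n_ovipositing": 17, "apop_mean": 4.6, "apop_se": 0.15, "aop_mean": 37.5, "aop_se": 4.66, "tpop_mean": 21.5},
    {"temperature_C": 34.9, "n_ovipositing": 11, "apop_mean": 6.2, "apop_se": 0.5, "aop_mean": 17.4, "aop_se": 1.55, "tpop_mean": 29.9}
  ],
  "degree_day": [
    {"trait": "male_longevity", "slope_a": 0.0023, "intercept_b": -0.0363, "r": 0.84, "ldt_C": 15.7, "tc_dd": 433.4},
    {"trait": "female_longevity", "slope_a": 0.002, "intercept_b": -0.0316, "r": 0.83, "ldt_C": 16.0, "tc_dd": 507.1},
    {"trait": "apop", "slope_a": 0.0126, "intercept_b": -0.1806, "r": 0.99, "ldt_C": 14.3, "tc_dd": 79.2},
    {"trait": "aop", "slope_a": 0.0014, "intercept_b": -0.0175, "r": 0.89, "ldt_C": 12.2, "tc_dd": 696.6},
    {"trait": "tpop", "slope_a": 0.0023, "intercept_b": -0.0241, "r": 0.97, "ldt_C": 10.6, "tc_dd": 437.4}
  ]
}
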