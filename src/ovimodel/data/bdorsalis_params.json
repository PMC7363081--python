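{
  "aging_female": {"r0": 0.0096, "T_H": 51.4995, "c": 4.8952},
  "aging_male": {"r0": 0.0093, "T_H": 52.1197, "c": 5.4531},
  "survival_female": {"alpha": 1.0921, "beta": 2.9417},
  "survival_male": {"alpha": 1.0665, "beta": 3.7744},
  "fecundity": {"alpha_f": 19.3991, "T_L": 16.3221, "T_H": 35.2481},
  "orm": {"gamma": 0.102, "eta": 0.2495, "beta": 1.2024},
  "pdrm": {"alpha_p": 0.00028177, "T_L": 13.3204, "T_H": 35.1973, "m": 4.4668},
  "pcdm": {"gamma": 0.4852, "eta": 0.453, "beta": 2.314},
  "odrm": {"a": 0.0393, "b": 1.99645e-17, "c": -12.7215, "d": 871175.0},
  "oorm": {"alpha": 0.2401, "beta": 1.0459}
}
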