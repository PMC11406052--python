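{
  "nano_qstr": {
    "response": "%EI_zebrafish",
    "intercept": 105.05,
    "intercept_se": 16.74,
    "coefficients": {"sum_chi": -5.66, "sum_alpha_sq": 0.14, "a0": -0.44},
    "coefficient_se": {"sum_chi": 1.94, "sum_alpha_sq": 0.04, "a0": 0.08},
    "stats": {"n_train": 16, "R2": 0.72, "R2_adj": 0.65, "Q2_LOO": 0.51,
              "n_test": 8, "R2_test": 0.72, "Q2_F1": 0.72, "Q2_F2": 0.70}
  },
  "nano_qrastr": {
    "response": "%EI_zebrafish",
    "intercept": -2.01,
    "intercept_se": 4.38,
    "coefficients": {"sum_alpha_sq": 0.17, "SE(LK)": 5.10, "CVsim(LK)": -10.93},
    "coefficient_se": {"sum_alpha_sq": 0.06, "SE(LK)": 0.84, "CVsim(LK)": 5.83},
    "stats": {"n_train": 16, "R2": 0.81, "R2_adj": 0.77, "Q2_LOO": 0.70,
              "n_test": 8, "R2_test": 0.81, "Q2_F1": 0.76, "Q2_F2": 0.74,
              "yrand_mean_R2": 0.20, "yrand_mean_Q2": -0.60, "yrand_n_iter": 100}
  }
}
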