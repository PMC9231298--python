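{
  "name": "brd4-ga-mlr-7d",
  "version": "1.0",
  "activity": "pIC50 (molar) against BRD-4",
  "intercept": 4.27,
  "intercept_se": 0.156,
  "coefficients": {
    "fsp3CringC2B": 0.093,
    "com_C_4A": 0.108,
    "Saturated_Carbo_Rings": 0.391,
    "fsulfonSaroC8B": 0.428,
    "flipoacc3B": 0.625,
    "fsp3OaroN6B": 0.921,
    "fplaNN4B": -0.367
  },
  "coefficient_se": {
    "fsp3CringC2B": 0.017,
    "com_C_4A": 0.014,
    "Saturated_Carbo_Rings": 0.066,
    "fsulfonSaroC8B": 0.036,
    "flipoacc3B": 0.059,
    "fsp3OaroN6B": 0.067,
    "fplaNN4B": 0.063
  },
  "n_training": 785,
  "n_external": 195,
  "h_star": 0.031,
  "training_statistics": {
    "r2_tr": 0.762,
    "r2_adj": 0.760,
    "rmse_tr": 0.389,
    "mae_tr": 0.326,
    "ccc_tr": 0.865,
    "s": 0.391,
    "F": 355.446,
    "q2_loo": 0.757,
    "rmse_cv": 0.393,
    "mae_cv": 0.329,
    "ccc_cv": 0.862,
    "q2_lmo": 0.756,
    "r2_yscr": 0.009,
    "q2_yscr": -0.012,
    "r2_ex": 0.762,
    "q2_f1": 0.762,
    "q2_f2": 0.760,
    "q2_f3": 0.758,
    "ccc_ex": 0.860,
    "rmse_ex": 0.392,
    "mae_ex": 0.323
  }
}
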