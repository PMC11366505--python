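{
  "Eq1": {
    "name": "Eq1",
    "response": "fecal",
    "intercept": -0.654,
    "coefficients": {"BW_SQ": -0.000618, "BWxDIETP": 0.273},
    "rmse": 0.656,
    "r2": 0.83,
    "fit_n": 95
  },
  "Eq2": {
    "name": "Eq2",
    "response": "urinary",
    "intercept": 0.045,
    "coefficients": {"BWxDIETP": 0.00781},
    "rmse": 0.194,
    "r2": 0.15,
    "fit_n": 95
  },
  "Eq3": {
    "name": "Eq3",
    "response": "total",
    "intercept": -0.598,
    "coefficients": {"BW_SQ": -0.000613, "BWxDIETP": 0.280},
    "rmse": 0.624,
    "r2": 0.86,
    "fit_n": 95
  },
  "Eq4": {
    "name": "Eq4",
    "response": "fecal",
    "intercept": -0.855,
    "coefficients": {"FIxDIETP": 5.35},
    "rmse": 0.572,
    "r2": 0.87,
    "fit_n": 95
  },
  "Eq5": {
    "name": "Eq5",
    "response": "urinary",
    "intercept": 0.023,
    "coefficients": {"FI": 0.11},
    "rmse": 0.198,
    "r2": 0.11,
    "fit_n": 95
  },
  "Eq6": {
    "name": "Eq6",
    "response": "total",
    "intercept": -0.842,
    "coefficients": {"FIxDIETP": 5.60},
    "rmse": 0.550,
    "r2": 0.89,
    "fit_n": 95
  }
}
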