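{
  "theta_hat1": 0.86,
  "assumed_true_theta": 0.28,
  "assumed_true_sigma2": 21.62,
  "a": 50.0,
  "b": 500.0,
  "alpha": 0.05,
  "beta": 0.2,
  "delta_design": -0.36,
  "sigma2_second": 24.96,
  "df_trial1": 60,
  "df_trial1_arms": 243
}
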