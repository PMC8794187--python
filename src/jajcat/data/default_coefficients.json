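{
 "note": "Published calibration of the JaJ explanatory model (general adult sample, N=244, static 14-item form). Fixed effects are on the logit scale; sigma is the participant random-intercept SD, anchored so the standardised length-2 difficulty equals 0.13 (sigma = 0.32/0.13).",
 "beta0": 0.86,
 "beta_l1": 1.44,
 "beta_len": -0.59,
 "sigma": 2.4615384615384617,
 "se": {"beta0": 0.21, "beta_l1": 0.19, "beta_len": 0.04}
}
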