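{
 "M": 5.8206,
 "k_IL6": 1.4528,
 "kappa_IL6": 0.6878,
 "V_JAK": 20000.0,
 "KM_JAK": 9999.9999,
 "kappa_JAK": 0.1695,
 "proSTAT3": 1.9108,
 "V_ST3": 749.9994,
 "KM_ST3": 0.1715,
 "kappa_ST3": 0.0828,
 "V_SOCS3": 24000.0,
 "KM_SOCS3": 0.0006,
 "kappa_SOCS3": 0.3173,
 "KI_SOCS3": 0.0153,
 "V_IE": 249.9992,
 "KM_IE": 17.9736,
 "kappa_IE": 4.9595,
 "k_deg": 6.9843,
 "kappa_ECM": 32.9924,
 "k_GF": 0.1014,
 "kappa_GF": 0.2016,
 "k_up": 0.0589,
 "k_QP": 0.0072,
 "k_PR": 0.0045,
 "k_RQ": 0.052,
 "k_prol": 0.0232,
 "k_req": 0.0912,
 "theta_req": 7.9493,
 "beta_req": 2.9285,
 "k_ap": 0.0982,
 "theta_ap": 0.0321,
 "beta_ap": 0.0045,
 "k_G": 0.0007
}
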