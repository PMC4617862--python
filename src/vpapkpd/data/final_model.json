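{
  "description": "Final mixed-effects logistic exposure-response model for >50% seizure-frequency reduction on valproic acid. Intercept-side coefficients in logit units (age per year); slope-side coefficients in logit per 100 ug/ml; omega2 is the between-subject random-effect variance.",
  "model_spec": {
    "form": "linear",
    "intercept_covariates": ["age", "CBZ", "CZP", "scn1a"],
    "slope_covariates": ["partial", "PHT", "TPM", "scn1a"]
  },
  "parameters": {
    "intercept": 6.09,
    "beta_age": 0.98,
    "beta_cbz_i": -1.75,
    "beta_czp_i": -1.18,
    "beta_ga_i": -5.87,
    "beta_aa_i": -4.88,
    "slope": -13.5,
    "beta_partial_s": 2.41,
    "beta_pht_s": -3.62,
    "beta_tpm_s": -1.73,
    "beta_ga_s": 10.1,
    "beta_aa_s": 9.48,
    "omega2": 11.3
  },
  "base_model_omega2": 12.9,
  "logit_cutoff": 0.1
}
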