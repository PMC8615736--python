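{
  "schema_version": 1,
  "model": {
    "feature_names": [
      "CATS2D_09_DA__me",
      "C-012__me",
      "VE1sign_D/Dt__bt",
      "F08[C-O]__me",
      "C-012__at",
      "VE2_D/Dt__me",
      "SpMAD_AEA(dm)__bt",
      "S-109__bt",
      "GATS3p__at",
      "HyWi_B(s)__bt"
    ],
    "intercept": 4.000,
    "coefficients": {
      "CATS2D_09_DA__me": 1.532,
      "C-012__me": 21.079,
      "VE1sign_D/Dt__bt": 6.037,
      "F08[C-O]__me": -0.546,
      "C-012__at": -17.982,
      "VE2_D/Dt__me": -52.531,
      "SpMAD_AEA(dm)__bt": 16.415,
      "S-109__bt": 5.531,
      "GATS3p__at": -7.509,
      "HyWi_B(s)__bt": -0.050
    },
    "wilks_lambda": 0.329,
    "f_stat": 212.86,
    "p_value": 1e-16,
    "standardized_coefficients": {},
    "feature_stats": {},
    "training_fingerprint": "",
    "n_training": 1059,
    "priors": "equal"
  },
  "averages": null,
  "conditions": [
    {"bt": "MNK-2", "me": "IC50", "at": "B"},
    {"bt": "MNK-1", "me": "IC50", "at": "B"},
    {"bt": "MNK-2", "me": "Kd", "at": "B"},
    {"bt": "MNK-1", "me": "Kd", "at": "B"},
    {"bt": "MNK-2", "me": "Ki", "at": "B"},
    {"bt": "MNK-1", "me": "Ki", "at": "B"},
    {"bt": "MNK-2", "me": "Ki", "at": "F"}
  ],
  "metadata": {
    "description": "Transcribed final two-isoform kinase-inhibition discriminant (PS3M-refined, 10 modified descriptors). Coefficients and intercept only: the artifact carries no average table or applicability-domain statistics, so it scores pre-modified descriptor rows with matching column names.",
    "selection": "fast-stepwise LDA refined by PS3M",
    "descriptor_engine": "external (AlvaDesc naming)"
  }
}
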