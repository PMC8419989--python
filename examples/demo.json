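{
 "seed": 5,
 "n_train": 86,
 "synth": {
  "n_features": 60,
  "n_discriminative": 4,
  "effect_size": 1.2,
  "n_scanner_shifted": 4,
  "shift_size": 1.0,
  "clinical_effect_size": 1.2,
  "seed": 5
 },
 "selection": {
  "alpha": 0.05,
  "modality_cap": 6,
  "fusion_cap": 8,
  "sfs_trees": 50,
  "cv": 5,
  "patience": 3
 },
 "model": {
  "n_trees": 500,
  "cv_folds": 10,
  "n_bootstrap": 1000
 }
}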