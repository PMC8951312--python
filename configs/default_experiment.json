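{
  "base_seed": 0,
  "classifier": {
    "C": 100000000000.0,
    "confidence_factor": 0.25,
    "gamma": 0.01,
    "hidden": 32,
    "k": 1,
    "kind": "svm_rbf",
    "learning_rate": 0.3,
    "seed": 0
  },
  "cohort": {
    "ar_order_gen": 5,
    "informative_channels": [
      1,
      4
    ],
    "n_channels": 8,
    "n_subjects": 4,
    "noise_sd": 10.0,
    "record_duration_s": 10.0,
    "records_per_subject": 6,
    "sampling_rate_hz": 160.0,
    "seed": 3
  },
  "feature": {
    "aggregate_segments": true,
    "method": "AR5",
    "wavelet_levels": 4,
    "wavelet_name": "db4",
    "wavelet_stats": [
      "energy",
      "mean_abs",
      "sd"
    ]
  },
  "fixed_split": false,
  "n_runs": 2,
  "optimizer": "fpa_bhc",
  "optimizer_cfg": {
    "D": 16,
    "N": 6,
    "T": 5,
    "beta": 0.5,
    "bhc_inner_iters": 3,
    "levy_lambda": 1.5,
    "levy_scale": 0.01,
    "max_evals": null,
    "p": 0.8,
    "seed": 0
  },
  "output_dir": null,
  "preprocess_cfg": null,
  "split_cfg": {
    "seed": 0,
    "stratified": true,
    "test_frac": 0.2,
    "train_frac": 0.5,
    "val_frac": 0.3
  }
}
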