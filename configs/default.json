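{
  "mode": "synthetic",
  "generator": {
    "n_subjects": 18,
    "n_sessions": 2,
    "n_channels": 46,
    "fs": 25.0,
    "duration": 660.0,
    "icc_target": 0.7,
    "noise_spec": {
      "cardiac_hz": 1.0,
      "cardiac_amp": 0.4,
      "respiratory_hz": 0.3,
      "respiratory_amp": 0.3,
      "mayer_hz": 0.1,
      "mayer_amp": 0.2,
      "instrument_sigma": 0.3,
      "freq_jitter": 0.01
    },
    "hbr_scale": -0.4,
    "seed": 0
  },
  "data_dir": null,
  "signals": [
    "HbO",
    "HbR",
    "HbT"
  ],
  "discard_seconds": 60.0,
  "ica": {
    "enabled": false,
    "variance_target": 0.99,
    "contrast": "skew",
    "max_iter": 500,
    "tol": 1e-05,
    "spectral_band": [
      0.01,
      0.1
    ],
    "jump_z": 6.0,
    "spike_z": 5.0,
    "min_spike_count": 10,
    "dispersion_fraction": 0.7
  },
  "filter": {
    "low_cut": 0.009,
    "high_cut": 0.08,
    "order": 4,
    "kind": "butter"
  },
  "sparsity_grid": [
    0.01,
    0.02,
    0.03,
    0.04,
    0.05,
    0.06,
    0.07,
    0.08,
    0.09,
    0.1,
    0.11,
    0.12,
    0.13,
    0.14,
    0.15,
    0.16,
    0.17,
    0.18,
    0.19,
    0.2,
    0.21,
    0.22,
    0.23,
    0.24,
    0.25,
    0.26,
    0.27,
    0.28,
    0.29,
    0.3,
    0.31,
    0.32,
    0.33,
    0.34,
    0.35,
    0.36,
    0.37,
    0.38,
    0.39,
    0.4,
    0.41,
    0.42,
    0.43,
    0.44,
    0.45,
    0.46,
    0.47,
    0.48,
    0.49,
    0.5,
    0.51,
    0.52,
    0.53,
    0.54,
    0.55,
    0.56,
    0.57,
    0.58,
    0.59,
    0.6,
    0.61,
    0.62,
    0.63,
    0.64,
    0.65,
    0.66,
    0.67,
    0.68,
    0.69,
    0.7,
    0.71,
    0.72,
    0.73,
    0.74,
    0.75,
    0.76,
    0.77,
    0.78,
    0.79,
    0.8,
    0.81,
    0.82,
    0.83,
    0.84,
    0.85,
    0.86,
    0.87,
    0.88,
    0.89,
    0.9,
    0.91,
    0.92,
    0.93,
    0.94,
    0.95,
    0.96,
    0.97,
    0.98,
    0.99
  ],
  "null": {
    "method": "topology_rewiring",
    "n_null": 100,
    "swaps_per_edge": 100,
    "seed": 0
  },
  "absolute_ranking": false,
  "out_dir": "results/run",
  "seed": 0,
  "log_level": "INFO"
}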