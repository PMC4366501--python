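{
  "coactivity": {
    "chi2": 1.939131982555347,
    "chi2_df": 2,
    "chi2_p": 0.3792475991563048,
    "distance_comparison": {
      "mannwhitney_u": 3122.5,
      "median_active_um": 48.687587678514646,
      "median_all_um": 46.111135561717774,
      "method": "asymptotic",
      "p_value": 0.9167723658243822
    },
    "expected_binned": [
      0.47813719744619115,
      1.2466645782609949,
      4.275198224292815
    ],
    "n_active_pairs": 17,
    "n_all_pairs": 373,
    "n_fovs": 6,
    "observed_binned": [
      1.0,
      0.0,
      5.0
    ],
    "p_response": 0.22388059701492538
  },
  "coupling": {
    "coupled_fraction": 0.4117647058823529,
    "n_coupled": 7,
    "n_determinate": 17,
    "n_indeterminate": 0,
    "n_pairs": 17,
    "spearman_p": 0.8736898095761171,
    "spearman_rho_p_vs_distance": -0.04171782281443676
  },
  "csrtest": {
    "area_multiplier": 1.0,
    "direction": "clustered",
    "n_points": 67,
    "n_replicates": 2000,
    "null_ci95_um": [
      13.065506827860972,
      16.94714971355899
    ],
    "null_mean_um": 14.965386016385713,
    "null_median_um": 14.959406812729057,
    "observed_mean_nnd_um": 12.60739407909602,
    "p_two_sided": 0.017991004497751123,
    "seed": 7
  }
}
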