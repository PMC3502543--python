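{
  "calls": {
    "adult_recall_intersection": {
      "jaccard": 0.8214285714285714,
      "n_a": 80,
      "n_b": 73,
      "n_intersection": 69
    },
    "false_discovery_proportion": 0.0,
    "n_gain": 80,
    "n_loss": 0,
    "n_neuronal": 39,
    "neuronal_sensitivity": 0.975,
    "sensitivity": 1.0
  },
  "clustering": {
    "results": {
      "d_1000000": {
        "direction": "greater",
        "fold_enrichment": 2.090738030524775,
        "n_sims": 2000,
        "null_mean": 38.264,
        "null_sd": 5.2597658282745,
        "observed": 80.0,
        "p": 0.0004997501249375312,
        "rng_seed": 282214483,
        "statistic": "pairing_lt_1000000bp"
      },
      "d_500000": {
        "direction": "greater",
        "fold_enrichment": 3.6017378385070797,
        "n_sims": 2000,
        "null_mean": 22.2115,
        "null_sd": 5.022985461005311,
        "observed": 80.0,
        "p": 0.0004997501249375312,
        "rng_seed": 662646145,
        "statistic": "pairing_lt_500000bp"
      }
    },
    "subset_size": 80
  },
  "footprint": {
    "archaic_postsplit_fraction": {
      "denisova": 0.033294163728946335,
      "neanderthal": 0.03179587831207066
    },
    "group_comparison": {
      "mean_a": 19.499215071025475,
      "mean_b": 7.051267913423521,
      "n_a": 80,
      "n_b": 32,
      "n_sims": 2000,
      "permutation_p": 0.0004997501249375312,
      "rng_seed": 1551122557,
      "sd_a": 2.7366574956197844,
      "sd_b": 1.7792967916011106,
      "wilcoxon_p": 1.7099963638258894e-16
    },
    "motif": {
      "chi2": {
        "chi2_pearson": 2.7757091046017286,
        "chi2_yates": 1.9656034728346572,
        "gained": 5,
        "gained_total": 79,
        "lost": 11,
        "lost_total": 76,
        "p_pearson": 0.09570426284874985,
        "p_yates": 0.16091530283664435
      },
      "gained": 5,
      "human_sites": 79,
      "lost": 11,
      "pattern": "WGATTAG",
      "shared_sites": 76
    },
    "n_blocks": 112,
    "n_hsas": 5199,
    "rate_control_mean": 7.051267913423521,
    "rate_gain_mean": 19.499215071025475,
    "substitution_fraction": 0.9669167147528371
  },
  "n_sims": 2000,
  "overlap": {
    "categories": {
      "both": {
        "direction": "greater",
        "fold_enrichment": 1.0707444183264598,
        "n_sims": 2000,
        "null_mean": 59.7715,
        "null_sd": 3.6541707995270363,
        "observed": 64.0,
        "p": 0.15092453773113443,
        "rng_seed": 400984836,
        "statistic": "overlap_both"
      },
      "neither": {
        "direction": "less",
        "fold_enrichment": 0.19243104554201412,
        "n_sims": 2000,
        "null_mean": 15.59,
        "null_sd": 3.4929930575725634,
        "observed": 3.0,
        "p": 0.0004997501249375312,
        "rng_seed": 1157077080,
        "statistic": "overlap_neither"
      },
      "other_only": {
        "direction": "less",
        "fold_enrichment": 0.0,
        "n_sims": 2000,
        "null_mean": 0.374,
        "null_sd": 0.588470176452713,
        "observed": 0.0,
        "p": 0.6771614192903548,
        "rng_seed": 2074454452,
        "statistic": "overlap_other_only"
      },
      "target_only": {
        "direction": "greater",
        "fold_enrichment": 3.1160115052732507,
        "n_sims": 2000,
        "null_mean": 4.172,
        "null_sd": 1.9535414410964107,
        "observed": 13.0,
        "p": 0.0004997501249375312,
        "rng_seed": 1423405360,
        "statistic": "overlap_target_only"
      }
    },
    "subset_size": 80
  },
  "seed": 17
}
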