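{
  "simulation": {
    "seed": 1,
    "n_taxon_groups": 5,
    "orfs_per_group": 400,
    "orf_length": 300,
    "read_length": 100,
    "dispersion": 0.05,
    "expr_log_sd": 1.0,
    "de_fraction": 0.1,
    "de_log2fc": 3.0,
    "de_sign": "both",
    "group_bloom_log2fc": [2.0, 1.0, 0.5, 0.0, 0.0],
    "subpop_divergence": 0.03,
    "subpop_mix": {"mid": 0.6, "late": 0.3},
    "error_rate": 0.002,
    "marker_log2fc": {
      "N": {"NRT2": 3.0, "GSII": -2.0},
      "Fe": {"ISIP1": 2.0, "ISIP2": 2.0, "ISIP3": 2.0, "thiC": 0.0}
    },
    "samples": [
      {"name": "MB1", "experiment": "N", "barrel": "B1", "condition": "mid", "library_size": 25000},
      {"name": "MB2", "experiment": "N", "barrel": "B1", "condition": "late", "library_size": 25000},
      {"name": "MB3", "experiment": "N", "barrel": "B3", "condition": "mid", "library_size": 25000},
      {"name": "MB4", "experiment": "N", "barrel": "B3", "condition": "late", "library_size": 25000},
      {"name": "MB5", "experiment": "Fe", "barrel": "B2", "condition": "mid", "library_size": 25000},
      {"name": "MB6", "experiment": "Fe", "barrel": "B2", "condition": "late", "library_size": 25000, "include_in_de": false},
      {"name": "MB7", "experiment": "Fe", "barrel": "B4", "condition": "mid", "library_size": 25000},
      {"name": "MB8", "experiment": "Fe", "barrel": "B4", "condition": "late", "library_size": 25000}
    ]
  },
  "de": {"min_total": 5},
  "pidshift": {"min_identity": 60.0, "alpha": 0.05, "min_reads": 10},
  "snv": {"min_depth": 4, "min_alt": 2, "min_af": 0.05, "sweep_hi": 0.9, "sweep_lo": 0.5},
  "cluster": {"k": 4, "min_shared": 3, "inflation": 1.5},
  "biomarker": {"pseudocount": 1.0}
}
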