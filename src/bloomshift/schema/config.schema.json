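{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "bloomshift pipeline configuration",
  "type": "object",
  "required": ["simulation"],
  "additionalProperties": false,
  "properties": {
    "simulation": {
      "type": "object",
      "additionalProperties": false,
      "properties": {
        "seed": {"type": "integer"},
        "n_taxon_groups": {"type": "integer", "minimum": 1},
        "orfs_per_group": {"type": "integer", "minimum": 1},
        "orf_length": {"type": "integer", "minimum": 30, "multipleOf": 3},
        "dispersion": {"type": "number", "minimum": 0},
        "expr_log_sd": {"type": "number", "minimum": 0},
        "de_fraction": {"type": "number", "minimum": 0, "maximum": 1},
        "de_log2fc": {"type": "number"},
        "de_sign": {"enum": ["both", "up", "down"]},
        "group_bloom_log2fc": {"type": ["array", "null"], "items": {"type": "number"}},
        "subpop_divergence": {"type": "number", "minimum": 0, "maximum": 0.3},
        "subpop_mix": {
          "type": "object",
          "additionalProperties": false,
          "properties": {
            "mid": {"type": "number", "minimum": 0, "maximum": 1},
            "late": {"type": "number", "minimum": 0, "maximum": 1}
          }
        },
        "error_rate": {"type": "number", "minimum": 0, "maximum": 0.05},
        "read_length": {"type": "integer", "minimum": 30},
        "marker_log2fc": {
          "type": "object",
          "additionalProperties": {"type": "object", "additionalProperties": {"type": "number"}}
        },
        "samples": {
          "type": "array",
          "items": {
            "type": "object",
            "required": ["name", "experiment", "barrel", "condition", "library_size"],
            "additionalProperties": false,
            "properties": {
              "name": {"type": "string"},
              "experiment": {"enum": ["N", "Fe"]},
              "barrel": {"type": "string"},
              "condition": {"enum": ["mid", "late"]},
              "library_size": {"type": "integer", "minimum": 1},
              "include_in_de": {"type": "boolean"}
            }
          }
        },
        "snv_spec": {
          "type": "array",
          "items": {
            "type": "object",
            "required": ["orf_id", "position", "ref_allele", "alt_allele", "freq_by_condition"],
            "additionalProperties": false,
            "properties": {
              "orf_id": {"type": "string"},
              "position": {"type": "integer", "minimum": 1},
              "ref_allele": {"enum": ["A", "C", "G", "T"]},
              "alt_allele": {"enum": ["A", "C", "G", "T"]},
              "freq_by_condition": {
                "type": "object",
                "additionalProperties": false,
                "properties": {
                  "mid": {"type": "number", "minimum": 0, "maximum": 1},
                  "late": {"type": "number", "minimum": 0, "maximum": 1}
                }
              }
            }
          }
        }
      }
    },
    "de": {
      "type": "object",
      "properties": {
        "min_total": {"type": "integer", "minimum": 0},
        "phi": {"type": ["number", "null"], "minimum": 0}
      }
    },
    "pidshift": {
      "type": "object",
      "properties": {
        "min_identity": {"type": "number"},
        "alpha": {"type": "number"},
        "min_reads": {"type": "integer"}
      }
    },
    "snv": {
      "type": "object",
      "properties": {
        "min_depth": {"type": "integer"},
        "min_alt": {"type": "integer"},
        "min_af": {"type": "number"},
        "sweep_hi": {"type": "number"},
        "sweep_lo": {"type": "number"}
      }
    },
    "cluster": {
      "type": "object",
      "properties": {
        "k": {"type": "integer"},
        "min_shared": {"type": "integer"},
        "inflation": {"type": "number"},
        "min_members": {"type": "integer"},
        "fc_threshold": {"type": "number"},
        "edge_list": {"type": "string"}
      }
    },
    "biomarker": {
      "type": "object",
      "properties": {
        "pseudocount": {"type": "number"},
        "include_dinoflagellates": {"type": "boolean"}
      }
    },
    "contrasts": {
      "type": ["object", "null"],
      "additionalProperties": {
        "type": "object",
        "properties": {
          "depleted": {"type": "array", "items": {"type": "string"}},
          "replete": {"type": "array", "items": {"type": "string"}}
        }
      }
    }
  }
}
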