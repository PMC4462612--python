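{
  "$defs": {
    "ExceedanceReport": {
      "properties": {
        "denominator": {
          "title": "Denominator",
          "type": "integer"
        },
        "fraction": {
          "title": "Fraction",
          "type": "number"
        },
        "numerator": {
          "title": "Numerator",
          "type": "integer"
        }
      },
      "required": [
        "fraction",
        "numerator",
        "denominator"
      ],
      "title": "ExceedanceReport",
      "type": "object"
    },
    "TopDmpEntry": {
      "properties": {
        "combined_score": {
          "title": "Combined Score",
          "type": "number"
        },
        "mean_delta": {
          "title": "Mean Delta",
          "type": "number"
        },
        "p_value": {
          "title": "P Value",
          "type": "number"
        },
        "probe_id": {
          "title": "Probe Id",
          "type": "string"
        },
        "rank": {
          "title": "Rank",
          "type": "integer"
        },
        "validated_vs_concordant": {
          "title": "Validated Vs Concordant",
          "type": "boolean"
        },
        "validated_vs_healthy": {
          "title": "Validated Vs Healthy",
          "type": "boolean"
        }
      },
      "required": [
        "probe_id",
        "p_value",
        "mean_delta",
        "combined_score",
        "rank",
        "validated_vs_concordant",
        "validated_vs_healthy"
      ],
      "title": "TopDmpEntry",
      "type": "object"
    }
  },
  "description": "Schema of the machine-readable run report (bundled as JSON schema).",
  "properties": {
    "config_hash": {
      "title": "Config Hash",
      "type": "string"
    },
    "enrichment_queries": {
      "additionalProperties": {
        "type": "integer"
      },
      "description": "query gene-list sizes per enriched list",
      "title": "Enrichment Queries",
      "type": "object"
    },
    "exceedance": {
      "$ref": "#/$defs/ExceedanceReport"
    },
    "feature_category_percentages": {
      "additionalProperties": {
        "additionalProperties": {
          "type": "number"
        },
        "type": "object"
      },
      "title": "Feature Category Percentages",
      "type": "object"
    },
    "group_pair_counts": {
      "additionalProperties": {
        "type": "integer"
      },
      "title": "Group Pair Counts",
      "type": "object"
    },
    "n_degenerate_probes": {
      "title": "N Degenerate Probes",
      "type": "integer"
    },
    "n_probes_dmp": {
      "title": "N Probes Dmp",
      "type": "integer"
    },
    "n_probes_input": {
      "title": "N Probes Input",
      "type": "integer"
    },
    "n_samples": {
      "title": "N Samples",
      "type": "integer"
    },
    "outputs": {
      "additionalProperties": {
        "type": "string"
      },
      "title": "Outputs",
      "type": "object"
    },
    "package_version": {
      "title": "Package Version",
      "type": "string"
    },
    "seed": {
      "title": "Seed",
      "type": "integer"
    },
    "top_dmps": {
      "items": {
        "$ref": "#/$defs/TopDmpEntry"
      },
      "title": "Top Dmps",
      "type": "array"
    },
    "venn_counts": {
      "additionalProperties": {
        "type": "integer"
      },
      "title": "Venn Counts",
      "type": "object"
    }
  },
  "required": [
    "package_version",
    "config_hash",
    "seed",
    "n_probes_input",
    "n_samples",
    "group_pair_counts",
    "n_probes_dmp",
    "n_degenerate_probes",
    "top_dmps",
    "venn_counts",
    "exceedance",
    "feature_category_percentages",
    "outputs"
  ],
  "title": "RunReport",
  "type": "object"
}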