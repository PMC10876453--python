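{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "orchid validity report",
  "type": "object",
  "required": [
    "score_summary",
    "component_correlations",
    "intake_correlations",
    "metric_correlations",
    "quartile_tables",
    "sex_tests",
    "sociodemographic_tests",
    "notes"
  ],
  "properties": {
    "score_summary": {
      "type": "object",
      "required": ["mean", "sd", "min", "max", "n"],
      "properties": {
        "mean": {"type": "number"},
        "sd": {"type": "number"},
        "min": {"type": "number"},
        "max": {"type": "number"},
        "n": {"type": "integer"}
      }
    },
    "component_correlations": {"$ref": "#/$defs/correlations"},
    "intake_correlations": {"$ref": "#/$defs/correlations"},
    "metric_correlations": {"$ref": "#/$defs/correlations"},
    "quartile_tables": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["variable", "quartile", "mean", "sd", "ci_low", "ci_high", "n"]
      }
    },
    "sex_tests": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["variable", "kind", "statistic", "p_value"]
      }
    },
    "sociodemographic_tests": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["variable", "kind", "statistic", "p_value"]
      }
    },
    "notes": {"type": "array", "items": {"type": "string"}}
  },
  "$defs": {
    "correlations": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["variable", "method", "r", "p_value", "n", "strength"],
        "properties": {
          "method": {"enum": ["spearman", "pearson"]},
          "r": {"type": ["number", "null"]},
          "p_value": {"type": ["number", "null"]},
          "strength": {"enum": ["high", "moderate", "low", "undefined"]}
        }
      }
    }
  }
}
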