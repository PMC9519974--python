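{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "psycop profile report",
  "type": "object",
  "required": ["fdr_q", "rdoc_map", "zprofile", "clustering", "anova",
               "manova", "manova_simple", "simple_effects", "cda",
               "cda_per_term"],
  "properties": {
    "fdr_q": {"type": "number", "exclusiveMinimum": 0, "maximum": 1},
    "rdoc_map": {
      "type": "object",
      "additionalProperties": {
        "enum": ["cognitive systems", "sensorimotor systems",
                 "positive valence", "negative valence",
                 "arousal/regulatory", "social processes"]
      }
    },
    "zprofile": {
      "type": "object",
      "required": ["columns", "rows", "values"],
      "properties": {
        "columns": {"type": "array", "items": {"type": "string"}},
        "rows": {"type": "array", "items": {"type": "string"}},
        "values": {
          "type": "array",
          "items": {"type": "array",
                    "items": {"type": ["number", "null"]}}
        }
      }
    },
    "clustering": {
      "type": "object",
      "required": ["linkage", "leaf_order", "labels"],
      "properties": {
        "linkage": {"type": "array",
                    "items": {"type": "array", "items": {"type": "number"},
                              "minItems": 4, "maxItems": 4}},
        "leaf_order": {"type": "array", "items": {"type": "integer"}},
        "labels": {"type": "array", "items": {"type": "string"}}
      }
    },
    "anova": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["variable", "term", "F", "df1", "df2", "p", "p_adj",
                     "stars"],
        "properties": {
          "variable": {"type": "string"},
          "term": {"enum": ["S", "A", "SxA"]},
          "F": {"type": ["number", "null"]},
          "df1": {"type": "integer"},
          "df2": {"type": "integer"},
          "p": {"type": ["number", "null"]},
          "p_adj": {"type": ["number", "null"]},
          "stars": {"enum": ["", "n.s.", "*", "**", "***"]}
        }
      }
    },
    "manova": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["term", "wilks", "F", "df1", "df2", "p", "p_adj"],
        "properties": {
          "term": {"enum": ["S", "A", "SxA"]},
          "wilks": {"type": "number", "exclusiveMinimum": 0, "maximum": 1}
        }
      }
    },
    "manova_simple": {
      "type": "object",
      "additionalProperties": {
        "type": "object",
        "required": ["wilks", "F", "df1", "df2", "p"]
      }
    },
    "simple_effects": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["variable", "contrast", "F", "df1", "df2", "p", "n"]
      }
    },
    "cda": {
      "type": "object",
      "required": ["eigenvalues", "percents", "canonical_correlations",
                   "raw_coefficients", "std_coefficients", "scores",
                   "group_means", "ellipses"],
      "properties": {
        "eigenvalues": {"type": "array", "items": {"type": "number",
                                                   "minimum": 0}},
        "percents": {"type": "array", "items": {"type": "number"}},
        "ellipses": {
          "type": "object",
          "additionalProperties": {
            "type": "object",
            "required": ["center", "semi_axes", "angle", "coverage"]
          }
        }
      }
    },
    "cda_per_term": {
      "type": "object",
      "additionalProperties": {
        "type": "object",
        "required": ["eigenvalues", "std_coefficients"]
      }
    }
  }
}
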