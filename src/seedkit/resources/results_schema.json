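{
  "type": "object",
  "required": [
    "tool",
    "version",
    "config",
    "normalization",
    "solutions",
    "status"
  ],
  "properties": {
    "tool": {"type": "string"},
    "version": {"type": "string"},
    "config": {"type": "object"},
    "normalization": {
      "type": "object",
      "required": ["split", "reversed", "deleted", "blocked_imports", "kept_imports"],
      "properties": {
        "split": {"type": "integer"},
        "reversed": {"type": "integer"},
        "deleted": {"type": "integer"},
        "blocked_imports": {"type": "integer"},
        "kept_imports": {"type": "integer"}
      }
    },
    "solutions": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["seeds", "ne_valid", "minimality"],
        "properties": {
          "seeds": {"type": "array", "items": {"type": "string"}},
          "ne_valid": {"type": "boolean"},
          "no_accumulation_valid": {"type": ["boolean", "null"]},
          "fba_flux": {"type": ["number", "null"]},
          "minimality": {
            "type": "string",
            "enum": ["ne_subset_minimal", "hybrid_subset_minimal", "cardinality_minimal"]
          }
        }
      }
    },
    "statistics": {"type": ["object", "null"]},
    "status": {
      "type": "string",
      "enum": [
        "exhausted",
        "solution_limit",
        "timeout",
        "unsatisfiable",
        "exhausted_without_valid"
      ]
    },
    "message": {"type": "string"}
  }
}
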