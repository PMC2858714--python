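{
  "type": "object",
  "required": [
    "threshold_label",
    "rule",
    "records_total",
    "records_suppressed",
    "percent_suppressed",
    "areas"
  ],
  "properties": {
    "threshold_label": {"type": "string", "enum": ["0%", "5%", "20%"]},
    "rule": {"type": "string", "enum": ["logit_model", "zero_uniqueness"]},
    "max_combs": {"type": "integer"},
    "records_total": {"type": "integer"},
    "records_suppressed": {"type": "integer"},
    "percent_suppressed": {"type": "number"},
    "areas": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["area", "n_records", "probability", "flagged"],
        "properties": {
          "area": {"type": "string"},
          "n_records": {"type": "integer"},
          "probability": {"type": "number"},
          "flagged": {"type": "boolean"}
        }
      }
    }
  }
}
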