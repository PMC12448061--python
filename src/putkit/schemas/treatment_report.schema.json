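{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "putkit treatment analysis report",
  "type": "object",
  "required": ["depth_gate_um", "groups", "paired_tests"],
  "properties": {
    "depth_gate_um": {
      "type": "array",
      "items": {"type": "number"},
      "minItems": 2,
      "maxItems": 2
    },
    "groups": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["side", "timepoint", "programmed_reduction_pct", "estimated_reduction_pct"],
        "properties": {
          "side": {"enum": ["top", "bottom"]},
          "timepoint": {"type": "string"},
          "programmed_reduction_pct": {"type": "number"},
          "estimated_reduction_pct": {"type": "number"}
        }
      }
    },
    "paired_tests": {
      "type": "object",
      "additionalProperties": {
        "type": "object",
        "required": ["t", "p", "n"],
        "properties": {
          "t": {"type": ["number", "null"]},
          "p": {"type": ["number", "null"]},
          "n": {"type": "integer"},
          "degenerate": {"type": "boolean"}
        }
      }
    }
  }
}
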