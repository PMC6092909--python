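{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "$id": "https://example.org/genotracks/columnar-json.schema.json",
  "title": "Columnar genomic data payload",
  "description": "Columnar representation of genomic data: parallel coordinate arrays (0-based half-open) plus named numeric value columns. All arrays have equal length; missing values are null.",
  "type": "object",
  "required": ["chr", "start", "end"],
  "properties": {
    "chr": {
      "type": "array",
      "items": { "type": "string", "minLength": 1 }
    },
    "start": {
      "type": "array",
      "items": { "type": "integer", "minimum": 0 }
    },
    "end": {
      "type": "array",
      "items": { "type": "integer", "minimum": 0 }
    },
    "values": {
      "type": "object",
      "additionalProperties": {
        "type": "array",
        "items": { "type": ["number", "null"] }
      }
    },
    "feature_names": {
      "description": "Optional per-row string labels (e.g. feature or peak names).",
      "type": "array",
      "items": { "type": "string" }
    },
    "counts": {
      "description": "Present on summarization responses: per-bin contribution counts per column.",
      "type": "object",
      "additionalProperties": {
        "type": "array",
        "items": { "type": "integer", "minimum": 0 }
      }
    }
  },
  "additionalProperties": false
}
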