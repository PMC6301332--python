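{
  "$schema": "http://json-schema.org/draft-07/schema#",
  "$id": "https://example.org/annalign/document.schema.json",
  "title": "Document",
  "description": "Document-centric annotation record: one abstract or paragraph with its text, ordered properties, and keyed entity/relation hash tables. Offsets are 0-based half-open Unicode code-point indices into `text`, which is NFC-normalized. Collections are serialized as newline-delimited JSON, one document per line, with canonical key ordering (sorted, except `properties` which preserves insertion order).",
  "type": "object",
  "required": ["doc_id", "text", "properties", "entities", "relations"],
  "additionalProperties": false,
  "properties": {
    "doc_id": {"type": "string", "minLength": 1},
    "text": {"type": "string"},
    "properties": {
      "type": "object",
      "additionalProperties": {"type": "string"}
    },
    "entities": {
      "type": "object",
      "additionalProperties": {"$ref": "#/definitions/entity"}
    },
    "relations": {
      "type": "object",
      "additionalProperties": {"$ref": "#/definitions/relation"}
    }
  },
  "definitions": {
    "entity": {
      "type": "object",
      "required": ["type", "start", "end", "surface", "tool", "norm_ids"],
      "additionalProperties": false,
      "properties": {
        "type": {
          "enum": ["gene", "protein", "mirna", "disease", "chemical", "mutation", "trigger", "outcome", "other"]
        },
        "start": {"type": "integer", "minimum": 0},
        "end": {"type": "integer", "exclusiveMinimum": 0},
        "surface": {"type": "string", "description": "must equal text[start:end]"},
        "tool": {"type": "string", "description": "producing tool; comma-joined after merging"},
        "norm_ids": {
          "type": "array",
          "items": {
            "type": "array",
            "items": {"type": "string"},
            "minItems": 2,
            "maxItems": 2,
            "description": "[source, identifier] pair, e.g. [\"NCBI_gene\", \"5728\"]"
          }
        }
      }
    },
    "relation": {
      "type": "object",
      "required": ["type", "tool", "arguments"],
      "additionalProperties": false,
      "properties": {
        "type": {"type": "string"},
        "tool": {"type": "string"},
        "arguments": {
          "type": "object",
          "minProperties": 1,
          "additionalProperties": {"type": "string", "description": "role -> entity key"}
        },
        "evidence_start": {"type": "integer", "minimum": 0},
        "evidence_end": {"type": "integer", "exclusiveMinimum": 0}
      },
      "dependencies": {
        "evidence_start": ["evidence_end"],
        "evidence_end": ["evidence_start"]
      }
    }
  }
}
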