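{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "Project definition (JSON mirror of the XML dialect, version 1)",
  "type": "object",
  "required": ["name", "forms"],
  "properties": {
    "dialect": {"type": "string"},
    "name": {"type": "string"},
    "title": {"type": "string"},
    "version": {"type": "string"},
    "visibility": {"enum": ["public", "private"]},
    "extra_attrs": {"type": "object", "additionalProperties": {"type": "string"}},
    "extensions": {"type": "array", "items": {"type": "string"}},
    "forms": {
      "type": "array",
      "minItems": 1,
      "items": {
        "type": "object",
        "required": ["id", "fields"],
        "properties": {
          "id": {"type": "string"},
          "title": {"type": "string"},
          "key": {"type": "string"},
          "level": {"type": "integer", "minimum": 1},
          "branch_of": {"type": "string"},
          "branch_at": {"type": "string"},
          "extra_attrs": {"type": "object", "additionalProperties": {"type": "string"}},
          "extensions": {"type": "array", "items": {"type": "string"}},
          "fields": {
            "type": "array",
            "items": {
              "type": "object",
              "required": ["id", "type", "label"],
              "properties": {
                "id": {"type": "string"},
                "type": {
                  "enum": [
                    "text", "long_text", "dropdown", "checkbox", "radio",
                    "location", "image", "video", "audio", "barcode",
                    "branch_trigger"
                  ]
                },
                "label": {"type": "string"},
                "required": {"type": "boolean"},
                "numeric": {"enum": ["none", "integer", "decimal"]},
                "min": {"type": ["number", "null"]},
                "max": {"type": ["number", "null"]},
                "date": {"type": ["string", "null"]},
                "regex": {"type": ["string", "null"]},
                "double_entry": {"type": "boolean"},
                "chartable": {"type": "boolean"},
                "choices": {
                  "type": "array",
                  "items": {
                    "type": "object",
                    "required": ["name", "value"],
                    "properties": {
                      "name": {"type": "string"},
                      "value": {"type": "string", "minLength": 1}
                    }
                  }
                },
                "jumps": {
                  "type": "array",
                  "items": {
                    "type": "object",
                    "required": ["when", "to"],
                    "properties": {
                      "when": {"type": "array", "items": {"type": "string"}},
                      "to": {"type": "string"}
                    }
                  }
                },
                "extra_attrs": {"type": "object", "additionalProperties": {"type": "string"}},
                "extensions": {"type": "array", "items": {"type": "string"}}
              }
            }
          }
        }
      }
    }
  }
}
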