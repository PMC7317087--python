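{
  "$schema": "http://json-schema.org/draft-07/schema#",
  "title": "biotracks package descriptor",
  "type": "object",
  "required": ["name", "profile", "resources", "biotracks"],
  "properties": {
    "name": {"type": "string", "minLength": 1},
    "profile": {"type": "string"},
    "resources": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["name", "path", "schema"],
        "properties": {
          "name": {"type": "string", "minLength": 1},
          "path": {"type": "string", "minLength": 1},
          "format": {"type": "string"},
          "mediatype": {"type": "string"},
          "schema": {
            "type": "object",
            "required": ["fields"],
            "properties": {
              "fields": {
                "type": "array",
                "items": {
                  "type": "object",
                  "required": ["name"],
                  "properties": {
                    "name": {"type": "string", "minLength": 1},
                    "type": {"type": "string", "enum": ["integer", "number", "string"]},
                    "constraints": {"type": "object"}
                  }
                }
              }
            }
          }
        }
      }
    },
    "biotracks": {
      "type": "object",
      "required": ["format_version", "bindings"],
      "properties": {
        "format_version": {"type": "string"},
        "bindings": {
          "type": "object",
          "required": ["object_id", "frame", "x", "y"],
          "additionalProperties": {"type": "string"}
        },
        "spatial_unit": {"type": "string"},
        "frame_interval": {"type": "number", "exclusiveMinimum": 0}
      }
    },
    "miacme": {"type": "object"}
  }
}
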