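{
  "$schema": "http://json-schema.org/draft-07/schema#",
  "title": "MIACME 1.1 experiment metadata (three conceptual domains)",
  "type": "object",
  "required": ["miacme_version"],
  "additionalProperties": true,
  "definitions": {
    "term": {
      "type": "object",
      "required": ["label"],
      "properties": {
        "label": {"type": "string", "minLength": 1},
        "source": {"type": "string"},
        "accession": {"type": "string"}
      },
      "dependencies": {"accession": ["source"]}
    },
    "termOrList": {
      "anyOf": [
        {"$ref": "#/definitions/term"},
        {"type": "array", "items": {"$ref": "#/definitions/term"}, "minItems": 1}
      ]
    },
    "positiveInt": {"type": "integer", "minimum": 1}
  },
  "properties": {
    "miacme_version": {"type": "string"},
    "investigation": {
      "type": "object",
      "properties": {
        "title": {"type": "string", "minLength": 1},
        "description": {"type": "string"},
        "studies": {"type": "array", "items": {"type": "object"}},
        "publications": {"type": "array", "items": {"type": "object"}},
        "people": {"type": "array", "items": {"type": "object"}},
        "organizations": {"type": "array", "items": {"type": "object"}},
        "grants": {"type": "array", "items": {"type": "object"}}
      }
    },
    "experimental_setup": {
      "type": "object",
      "properties": {
        "assay_type": {"$ref": "#/definitions/term"},
        "cell_model": {"$ref": "#/definitions/termOrList"},
        "cell_input": {
          "anyOf": [{"type": "string", "minLength": 1},
                    {"$ref": "#/definitions/term"}]
        },
        "environment": {"type": "object"},
        "perturbations": {
          "type": "array",
          "items": {
            "type": "object",
            "properties": {
              "agent": {"anyOf": [{"type": "string", "minLength": 1},
                                  {"$ref": "#/definitions/term"}]},
              "dose": {"type": "number"},
              "dose_unit": {"type": "string"}
            }
          }
        }
      }
    },
    "imaging_condition": {
      "type": "object",
      "properties": {
        "modality": {"$ref": "#/definitions/term"},
        "instrument": {"type": "string"},
        "channels": {"type": "array", "items": {"type": "object"}},
        "time_interval": {"type": "number", "exclusiveMinimum": 0},
        "time_interval_unit": {"type": "string"},
        "duration": {"type": "number"},
        "pixel_size": {"type": "number"},
        "pixel_size_unit": {"type": "string"}
      }
    },
    "data": {
      "type": "object",
      "properties": {
        "raw_data_summary": {
          "type": "object",
          "properties": {
            "number_of_images": {"$ref": "#/definitions/positiveInt"},
            "image_dimensions": {"type": "string"},
            "number_of_replicates": {"$ref": "#/definitions/positiveInt"}
          }
        },
        "processed_data": {"type": "array", "items": {"type": "object"}},
        "analysis_outputs": {"type": "array", "items": {"type": "object"}}
      }
    }
  }
}
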