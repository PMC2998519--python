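{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "pathnet repository document",
  "description": "Four-layer pathway-network repository: vocabularies, entities, localized entities, interactions and pathways. This schema documents the format accepted by pathnet.load_repository; validation in the library is performed by pathnet.schema.validate_document, which additionally enforces per-collection id uniqueness.",
  "type": "object",
  "required": [
    "format_version", "organisms", "entity_types", "interaction_types",
    "cell_locations", "pathway_classes", "entities", "local_entities",
    "interactions", "pathways"
  ],
  "additionalProperties": false,
  "properties": {
    "format_version": {"const": "1.0"},
    "organisms": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["id", "name"],
        "additionalProperties": false,
        "properties": {
          "id": {"type": "string", "minLength": 1},
          "name": {"type": "string"}
        }
      }
    },
    "entity_types": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["id", "label"],
        "additionalProperties": false,
        "properties": {
          "id": {"type": "string", "minLength": 1},
          "label": {"type": "string"}
        }
      }
    },
    "interaction_types": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["id", "label", "is_regulatory"],
        "additionalProperties": false,
        "properties": {
          "id": {"type": "string", "minLength": 1},
          "label": {"type": "string"},
          "is_regulatory": {"type": "boolean"}
        }
      }
    },
    "cell_locations": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["id", "name"],
        "additionalProperties": false,
        "properties": {
          "id": {"type": "string", "minLength": 1},
          "name": {"type": "string"},
          "parent": {"type": ["string", "null"]}
        }
      }
    },
    "pathway_classes": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["id", "name"],
        "additionalProperties": false,
        "properties": {
          "id": {"type": "string", "minLength": 1},
          "name": {"type": "string"},
          "parent": {"type": ["string", "null"]}
        }
      }
    },
    "entities": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["id", "name", "entity_type"],
        "additionalProperties": false,
        "properties": {
          "id": {"type": "string", "minLength": 1},
          "name": {"type": "string"},
          "entity_type": {"type": "string"},
          "organism": {"type": ["string", "null"]},
          "synonyms": {"type": "array", "items": {"type": "string"}}
        }
      }
    },
    "local_entities": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["id", "entity", "location"],
        "additionalProperties": false,
        "properties": {
          "id": {"type": "string", "minLength": 1},
          "entity": {"type": "string"},
          "location": {"type": "string"}
        }
      }
    },
    "interactions": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["id", "interaction_type", "participants"],
        "additionalProperties": false,
        "properties": {
          "id": {"type": "string", "minLength": 1},
          "interaction_type": {"type": "string"},
          "organism": {"type": ["string", "null"]},
          "participants": {
            "type": "array",
            "minItems": 1,
            "items": {
              "type": "object",
              "required": ["local_entity", "role"],
              "additionalProperties": false,
              "properties": {
                "local_entity": {"type": "string"},
                "role": {"enum": ["input", "output", "modifier"]},
                "modifier_effect": {
                  "enum": ["catalysis", "activation", "inhibition", null]
                },
                "stoichiometry": {"type": "number", "exclusiveMinimum": 0}
              }
            }
          }
        }
      }
    },
    "pathways": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["id", "name", "organism", "interactions"],
        "additionalProperties": false,
        "properties": {
          "id": {"type": "string", "minLength": 1},
          "name": {"type": "string"},
          "organism": {"type": "string"},
          "pathway_class": {"type": ["string", "null"]},
          "interactions": {
            "type": "array",
            "items": {"type": "string"},
            "uniqueItems": true
          }
        }
      }
    }
  }
}
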