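{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "preterm-cascade scenario library",
  "type": "object",
  "additionalProperties": false,
  "required": ["scenarios"],
  "$defs": {
    "setting": {"enum": ["home", "clinic", "hospital"]},
    "subconditionName": {
      "enum": ["RDS", "IVH", "NEC", "sepsis", "birth_asphyxia", "LBW_only"]
    },
    "boost": {
      "type": "object",
      "additionalProperties": false,
      "required": ["name"],
      "properties": {
        "name": {"type": "string"},
        "settings": {"type": "array", "items": {"$ref": "#/$defs/setting"}}
      }
    }
  },
  "properties": {
    "scenarios": {
      "type": "array",
      "items": {
        "type": "object",
        "additionalProperties": false,
        "required": ["id", "table", "number", "description", "subcondition_filter"],
        "properties": {
          "id": {"type": "string"},
          "table": {"enum": [3, 4]},
          "number": {"type": "integer", "minimum": 1},
          "description": {"type": "string"},
          "boost_mode": {"enum": ["none", "incremental", "universal", "both"]},
          "boosted_profiles": {"type": "array", "items": {"$ref": "#/$defs/boost"}},
          "boosted_gates": {"type": "array", "items": {"$ref": "#/$defs/boost"}},
          "transfer_gates": {"type": "array", "items": {"type": "string"}},
          "transfer_destination": {"$ref": "#/$defs/setting"},
          "location_override": {
            "type": "object",
            "propertyNames": {"$ref": "#/$defs/setting"},
            "additionalProperties": {"type": "number", "minimum": 0, "maximum": 1}
          },
          "subcondition_filter": {
            "type": "array",
            "items": {"$ref": "#/$defs/subconditionName"},
            "minItems": 1
          }
        }
      }
    }
  }
}
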