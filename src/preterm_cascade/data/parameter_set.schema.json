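{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "preterm-cascade parameter set",
  "description": "Schema of the YAML/JSON parameter configs accepted by load_parameter_set. Probability-valued fields are percentages when units=percent, proportions otherwise.",
  "type": "object",
  "additionalProperties": false,
  "required": ["population", "subconditions", "diagnostics", "interventions"],
  "$defs": {
    "prob": {"type": "number", "minimum": 0},
    "perSetting": {
      "type": "object",
      "additionalProperties": false,
      "required": ["home", "clinic", "hospital"],
      "properties": {
        "home": {"$ref": "#/$defs/prob"},
        "clinic": {"$ref": "#/$defs/prob"},
        "hospital": {"$ref": "#/$defs/prob"}
      }
    },
    "subconditionName": {
      "enum": ["RDS", "IVH", "NEC", "sepsis", "birth_asphyxia", "LBW_only"]
    },
    "setting": {"enum": ["home", "clinic", "hospital"]}
  },
  "properties": {
    "schema_version": {"const": 1},
    "units": {"enum": ["percent", "proportion"]},
    "name": {"type": "string"},
    "population": {
      "type": "object",
      "additionalProperties": false,
      "required": ["n_preterm_births", "delivery_mix", "anc_mix"],
      "properties": {
        "n_preterm_births": {"type": "integer", "exclusiveMinimum": 0},
        "delivery_mix": {"$ref": "#/$defs/perSetting"},
        "anc_mix": {"$ref": "#/$defs/perSetting"}
      }
    },
    "subconditions": {
      "type": "object",
      "propertyNames": {"$ref": "#/$defs/subconditionName"},
      "additionalProperties": {
        "type": "object",
        "additionalProperties": false,
        "required": ["prevalence", "untreated_cfr"],
        "properties": {
          "prevalence": {"$ref": "#/$defs/prob"},
          "untreated_cfr": {"$ref": "#/$defs/prob"}
        }
      }
    },
    "diagnostics": {
      "type": "object",
      "additionalProperties": {
        "type": "object",
        "additionalProperties": false,
        "required": ["penetration", "utilization", "efficacy"],
        "properties": {
          "penetration": {"$ref": "#/$defs/perSetting"},
          "utilization": {"$ref": "#/$defs/perSetting"},
          "efficacy": {"$ref": "#/$defs/perSetting"},
          "role": {"const": "diagnostic"},
          "target": {
            "oneOf": [{"$ref": "#/$defs/subconditionName"}, {"type": "null"}]
          }
        }
      }
    },
    "interventions": {
      "type": "object",
      "additionalProperties": {
        "type": "object",
        "additionalProperties": false,
        "required": ["role", "timing", "applicable_settings", "penetration", "utilization", "efficacy", "gates"],
        "properties": {
          "role": {"enum": ["preventive", "treatment"]},
          "timing": {"enum": ["antenatal", "delivery", "postnatal"]},
          "at_birth": {"type": "boolean"},
          "applicable_settings": {
            "type": "array",
            "items": {"$ref": "#/$defs/setting"},
            "minItems": 1
          },
          "penetration": {"$ref": "#/$defs/perSetting"},
          "utilization": {"$ref": "#/$defs/perSetting"},
          "efficacy": {
            "type": "object",
            "propertyNames": {"$ref": "#/$defs/subconditionName"},
            "additionalProperties": {"$ref": "#/$defs/prob"},
            "minProperties": 1
          },
          "gates": {
            "type": "object",
            "propertyNames": {"$ref": "#/$defs/subconditionName"},
            "additionalProperties": {"oneOf": [{"type": "string"}, {"type": "null"}]}
          }
        }
      }
    },
    "transfer": {
      "type": "object",
      "additionalProperties": false,
      "properties": {
        "destination": {"$ref": "#/$defs/setting"},
        "rates": {
          "type": "object",
          "additionalProperties": {"$ref": "#/$defs/perSetting"}
        }
      }
    },
    "coverage_cap": {"$ref": "#/$defs/prob"},
    "antenatal_weighting": {"enum": ["anc_mix", "delivery_mix"]}
  }
}
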