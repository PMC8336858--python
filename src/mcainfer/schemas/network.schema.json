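{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "$id": "mcainfer-network/1",
  "title": "mcainfer metabolic network",
  "type": "object",
  "required": ["metabolites", "reactions"],
  "properties": {
    "schema": {"const": "mcainfer-network/1"},
    "metabolites": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["id"],
        "properties": {
          "id": {"type": "string"},
          "name": {"type": "string"},
          "internal": {"type": "boolean", "default": true},
          "moiety_group": {"type": ["string", "null"], "default": null}
        }
      }
    },
    "reactions": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["id", "stoichiometry"],
        "properties": {
          "id": {"type": "string"},
          "stoichiometry": {
            "type": "object",
            "additionalProperties": {"type": "number"},
            "minProperties": 1,
            "description": "metabolite id -> signed coefficient (negative = substrate)"
          },
          "net_flux": {"type": "number", "default": 1.0},
          "rho": {
            "type": "number",
            "minimum": 0,
            "exclusiveMaximum": 1,
            "default": 0,
            "description": "disequilibrium ratio vr/vf for the net-flux-positive orientation"
          },
          "modifiers": {
            "type": "array",
            "items": {
              "type": "array",
              "prefixItems": [
                {"type": "string"},
                {"enum": ["activator", "inhibitor"]}
              ],
              "minItems": 2,
              "maxItems": 2
            }
          },
          "competitive_pairs": {
            "type": "array",
            "items": {
              "type": "array",
              "items": {"type": "string"},
              "minItems": 2,
              "maxItems": 2,
              "description": "[substrate id, product id]"
            }
          },
          "elasticity_upper": {
            "type": "object",
            "additionalProperties": {"type": "number", "exclusiveMinimum": 0},
            "description": "per-reactant Hill-type saturation bound h (default 1)"
          },
          "boundary": {"type": "boolean", "default": false}
        }
      }
    },
    "moieties": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["id", "members"],
        "properties": {
          "id": {"type": "string"},
          "members": {"type": "array", "items": {"type": "string"}, "minItems": 2},
          "concentration_ratios": {
            "type": "object",
            "additionalProperties": {"type": "number", "exclusiveMinimum": 0},
            "description": "keys 'A/B'; the ratio graph must connect all members"
          }
        }
      }
    },
    "couplings": {
      "type": "array",
      "items": {
        "type": "array",
        "items": {"type": "string"},
        "minItems": 2,
        "description": "reaction ids whose dlog activities are constrained equal"
      }
    }
  }
}
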