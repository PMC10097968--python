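{
  "$defs": {
    "Basis": {
      "enum": [
        "per-serving",
        "per-100g",
        "per-100mL"
      ],
      "title": "Basis",
      "type": "string"
    },
    "Category": {
      "enum": [
        "dairy",
        "juice",
        "ice-cream",
        "culinary",
        "beverage",
        "other"
      ],
      "title": "Category",
      "type": "string"
    },
    "Component": {
      "additionalProperties": true,
      "properties": {
        "id": {
          "title": "Id",
          "type": "string"
        },
        "name": {
          "title": "Name",
          "type": "string"
        },
        "mass_fraction": {
          "maximum": 1.0,
          "minimum": 0.0,
          "title": "Mass Fraction",
          "type": "number"
        },
        "ingredient_statement": {
          "anyOf": [
            {
              "type": "string"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "Ingredient Statement"
        },
        "profile": {
          "anyOf": [
            {
              "$ref": "#/$defs/NutrientProfile"
            },
            {
              "type": "null"
            }
          ],
          "default": null
        },
        "provenance": {
          "$ref": "#/$defs/Provenance",
          "default": "declared"
        },
        "subcomponents": {
          "items": {
            "$ref": "#/$defs/Component"
          },
          "title": "Subcomponents",
          "type": "array"
        }
      },
      "required": [
        "id",
        "name",
        "mass_fraction"
      ],
      "title": "Component",
      "type": "object"
    },
    "NutrientProfile": {
      "additionalProperties": false,
      "description": "Quantities keyed by controlled-vocabulary nutrient id, one basis.",
      "properties": {
        "basis": {
          "$ref": "#/$defs/Basis"
        },
        "quantities": {
          "additionalProperties": {
            "type": "number"
          },
          "title": "Quantities",
          "type": "object"
        }
      },
      "required": [
        "basis"
      ],
      "title": "NutrientProfile",
      "type": "object"
    },
    "Provenance": {
      "enum": [
        "assayed",
        "declared",
        "reference-substituted"
      ],
      "title": "Provenance",
      "type": "string"
    }
  },
  "additionalProperties": true,
  "description": "Formal schema for single-product JSON documents. Nutrient ids and their canonical units come from the controlled vocabulary in nutrients.json. Semantic invariants (species sums, mass-fraction sums, depth cap) are enforced by the validator beyond this structural schema.",
  "properties": {
    "id": {
      "title": "Id",
      "type": "string"
    },
    "name": {
      "title": "Name",
      "type": "string"
    },
    "category": {
      "$ref": "#/$defs/Category"
    },
    "serving_size": {
      "exclusiveMinimum": 0.0,
      "title": "Serving Size",
      "type": "number"
    },
    "serving_unit": {
      "default": "g",
      "title": "Serving Unit",
      "type": "string"
    },
    "servings_per_package": {
      "default": 1,
      "minimum": 1,
      "title": "Servings Per Package",
      "type": "integer"
    },
    "ingredient_statement": {
      "default": "",
      "title": "Ingredient Statement",
      "type": "string"
    },
    "components": {
      "items": {
        "$ref": "#/$defs/Component"
      },
      "title": "Components",
      "type": "array"
    },
    "declared_profile": {
      "anyOf": [
        {
          "$ref": "#/$defs/NutrientProfile"
        },
        {
          "type": "null"
        }
      ],
      "default": null
    },
    "claims": {
      "items": {
        "type": "string"
      },
      "title": "Claims",
      "type": "array"
    },
    "whitelist_ids": {
      "items": {
        "type": "string"
      },
      "title": "Whitelist Ids",
      "type": "array"
    }
  },
  "required": [
    "id",
    "name",
    "category",
    "serving_size"
  ],
  "title": "foodtiers product document",
  "type": "object",
  "$schema": "https://json-schema.org/draft/2020-12/schema"
}
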