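{
  "$defs": {
    "FunctionSpec": {
      "additionalProperties": false,
      "description": "One of the four NHRS functions and its ordered indicator ids.",
      "properties": {
        "id": {
          "minLength": 1,
          "title": "Id",
          "type": "string"
        },
        "indicator_ids": {
          "items": {
            "type": "string"
          },
          "title": "Indicator Ids",
          "type": "array"
        },
        "name": {
          "title": "Name",
          "type": "string"
        }
      },
      "required": [
        "id",
        "name",
        "indicator_ids"
      ],
      "title": "FunctionSpec",
      "type": "object"
    },
    "GoalpostSource": {
      "enum": [
        "fixed",
        "cohort_max",
        "policy_target"
      ],
      "title": "GoalpostSource",
      "type": "string"
    },
    "IndicatorKind": {
      "enum": [
        "binary",
        "continuous"
      ],
      "title": "IndicatorKind",
      "type": "string"
    },
    "IndicatorSpec": {
      "additionalProperties": false,
      "description": "One sub-function of the barometer.\n\n``order`` keeps the conventional 1\u201317 numbering as a display attribute;\nthe stable identity is the machine slug ``id``, so schemas can be edited\nwithout renumbering.",
      "properties": {
        "benchmark_note": {
          "anyOf": [
            {
              "type": "string"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "Benchmark Note"
        },
        "function_id": {
          "title": "Function Id",
          "type": "string"
        },
        "goalpost_max": {
          "title": "Goalpost Max",
          "type": "number"
        },
        "goalpost_min": {
          "minimum": 0,
          "title": "Goalpost Min",
          "type": "number"
        },
        "goalpost_source": {
          "$ref": "#/$defs/GoalpostSource",
          "default": "fixed"
        },
        "id": {
          "minLength": 1,
          "title": "Id",
          "type": "string"
        },
        "kind": {
          "$ref": "#/$defs/IndicatorKind"
        },
        "label": {
          "title": "Label",
          "type": "string"
        },
        "order": {
          "default": 0,
          "title": "Order",
          "type": "integer"
        },
        "scaling": {
          "$ref": "#/$defs/Scaling",
          "default": "none"
        }
      },
      "required": [
        "id",
        "label",
        "function_id",
        "kind",
        "goalpost_min",
        "goalpost_max"
      ],
      "title": "IndicatorSpec",
      "type": "object"
    },
    "Scaling": {
      "description": "How a raw observation becomes the indicator's actual score.",
      "enum": [
        "none",
        "per_100k_population",
        "per_million_population",
        "percent_of_total_budget"
      ],
      "title": "Scaling",
      "type": "string"
    }
  },
  "additionalProperties": false,
  "description": "A complete barometer definition.\n\nIndicators are stored as an ordered list (the file format); the\n``indicator_map`` property gives id-keyed access. Structural invariants\n(partition of indicators across functions, goalpost ordering, binary\ngoalpost conventions) are checked by :func:`validate_schema` rather\nthan at construction, so that invalid schemas can be represented and\nreported on.",
  "properties": {
    "functions": {
      "items": {
        "$ref": "#/$defs/FunctionSpec"
      },
      "title": "Functions",
      "type": "array"
    },
    "indicators": {
      "items": {
        "$ref": "#/$defs/IndicatorSpec"
      },
      "title": "Indicators",
      "type": "array"
    },
    "name": {
      "title": "Name",
      "type": "string"
    },
    "version": {
      "default": "1.0",
      "title": "Version",
      "type": "string"
    }
  },
  "required": [
    "name",
    "functions",
    "indicators"
  ],
  "title": "BarometerSchema",
  "type": "object"
}
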