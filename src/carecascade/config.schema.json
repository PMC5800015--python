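{
  "$defs": {
    "FilterSpec": {
      "additionalProperties": false,
      "description": "One stage of the care pathway.\n\nParameters\n----------\nname:\n    Identifier, unique within a scenario.\ndescription:\n    Free-text account of how the stage operates (e.g. \"Clinician\n    judgement\", \"Computerised short screening tool\").\npass_rate:\n    Fraction of stage entrants who pass, in [0, 1].\nunit_cost:\n    Non-negative cost charged for every person *entering* the stage.",
      "properties": {
        "name": {
          "minLength": 1,
          "title": "Name",
          "type": "string"
        },
        "description": {
          "default": "",
          "title": "Description",
          "type": "string"
        },
        "pass_rate": {
          "maximum": 1.0,
          "minimum": 0.0,
          "title": "Pass Rate",
          "type": "number"
        },
        "unit_cost": {
          "minimum": 0.0,
          "title": "Unit Cost",
          "type": "number"
        }
      },
      "required": [
        "name",
        "pass_rate",
        "unit_cost"
      ],
      "title": "FilterSpec",
      "type": "object"
    },
    "ScenarioSpec": {
      "additionalProperties": false,
      "description": "A complete cascade configuration.\n\n``population_size`` is the whole population screened conceptually\n(e.g. all cancer patients); ``prevalence`` the fraction with the\ntarget condition (e.g. depression).  Only the target group enters\nthe first filter and incurs costs.",
      "properties": {
        "scenario_id": {
          "minLength": 1,
          "title": "Scenario Id",
          "type": "string"
        },
        "label": {
          "default": "",
          "title": "Label",
          "type": "string"
        },
        "population_size": {
          "exclusiveMinimum": 0,
          "title": "Population Size",
          "type": "number"
        },
        "prevalence": {
          "maximum": 1.0,
          "minimum": 0.0,
          "title": "Prevalence",
          "type": "number"
        },
        "filters": {
          "items": {
            "$ref": "#/$defs/FilterSpec"
          },
          "minItems": 1,
          "title": "Filters",
          "type": "array"
        }
      },
      "required": [
        "scenario_id",
        "population_size",
        "prevalence",
        "filters"
      ],
      "title": "ScenarioSpec",
      "type": "object"
    }
  },
  "additionalProperties": false,
  "description": "A batch of scenarios with a designated baseline.\n\nWhen batch comparison is requested, scenarios are expected to share the\nsame filter-name sequence; a mismatch triggers a warning (comparisons\nremain meaningful via the final-stage success convention) rather than\nan error.",
  "properties": {
    "currency_symbol": {
      "default": "$",
      "title": "Currency Symbol",
      "type": "string"
    },
    "baseline_id": {
      "title": "Baseline Id",
      "type": "string"
    },
    "scenarios": {
      "items": {
        "$ref": "#/$defs/ScenarioSpec"
      },
      "minItems": 1,
      "title": "Scenarios",
      "type": "array"
    },
    "notes": {
      "default": "",
      "title": "Notes",
      "type": "string"
    }
  },
  "required": [
    "baseline_id",
    "scenarios"
  ],
  "title": "ModelConfig",
  "type": "object"
}
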