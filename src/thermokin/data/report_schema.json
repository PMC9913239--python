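{
  "$defs": {
    "AnalysisConfig": {
      "description": "Knobs of the analysis, logged verbatim into the report.",
      "properties": {
        "break_temperature_K": {
          "default": 316.15,
          "title": "Break Temperature K",
          "type": "number"
        },
        "delayed_mode": {
          "default": "free_intercept",
          "title": "Delayed Mode",
          "type": "string"
        },
        "gas_constant": {
          "default": 8.314,
          "title": "Gas Constant",
          "type": "number"
        },
        "r_above": {
          "default": 0.5,
          "title": "R Above",
          "type": "number"
        },
        "r_below": {
          "default": 0.25,
          "title": "R Below",
          "type": "number"
        },
        "recovery_h": {
          "default": 24.0,
          "title": "Recovery H",
          "type": "number"
        },
        "simple_mode": {
          "default": "through_origin",
          "title": "Simple Mode",
          "type": "string"
        }
      },
      "title": "AnalysisConfig",
      "type": "object"
    },
    "ArrheniusBlock": {
      "properties": {
        "activation_energy": {
          "title": "Activation Energy",
          "type": "number"
        },
        "gas_constant": {
          "title": "Gas Constant",
          "type": "number"
        },
        "ln_frequency_factor": {
          "title": "Ln Frequency Factor",
          "type": "number"
        },
        "r_squared": {
          "title": "R Squared",
          "type": "number"
        }
      },
      "required": [
        "ln_frequency_factor",
        "activation_energy",
        "gas_constant",
        "r_squared"
      ],
      "title": "ArrheniusBlock",
      "type": "object"
    },
    "CellLineBlock": {
      "properties": {
        "arrhenius": {
          "$ref": "#/$defs/ArrheniusBlock"
        },
        "arrhenius_delayed": {
          "$ref": "#/$defs/DelayedBlock"
        },
        "r_cem": {
          "anyOf": [
            {
              "type": "number"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "R Cem"
        },
        "two_state": {
          "$ref": "#/$defs/TwoStateBlock"
        }
      },
      "required": [
        "arrhenius",
        "arrhenius_delayed",
        "two_state"
      ],
      "title": "CellLineBlock",
      "type": "object"
    },
    "DelayedBlock": {
      "properties": {
        "activation_energy": {
          "title": "Activation Energy",
          "type": "number"
        },
        "gas_constant": {
          "title": "Gas Constant",
          "type": "number"
        },
        "intercept_b": {
          "title": "Intercept B",
          "type": "number"
        },
        "ln_frequency_factor": {
          "title": "Ln Frequency Factor",
          "type": "number"
        },
        "r_squared": {
          "title": "R Squared",
          "type": "number"
        },
        "slope_m": {
          "title": "Slope M",
          "type": "number"
        }
      },
      "required": [
        "ln_frequency_factor",
        "activation_energy",
        "gas_constant",
        "r_squared",
        "slope_m",
        "intercept_b"
      ],
      "title": "DelayedBlock",
      "type": "object"
    },
    "ModelComparisonRow": {
      "properties": {
        "model": {
          "title": "Model",
          "type": "string"
        },
        "recovery_h": {
          "title": "Recovery H",
          "type": "number"
        },
        "rmse_by_cell_line": {
          "additionalProperties": {
            "type": "number"
          },
          "title": "Rmse By Cell Line",
          "type": "object"
        },
        "rmse_pct": {
          "minimum": 0,
          "title": "Rmse Pct",
          "type": "number"
        }
      },
      "required": [
        "model",
        "recovery_h",
        "rmse_pct",
        "rmse_by_cell_line"
      ],
      "title": "ModelComparisonRow",
      "type": "object"
    },
    "TwoStateBlock": {
      "properties": {
        "alpha": {
          "title": "Alpha",
          "type": "number"
        },
        "beta": {
          "title": "Beta",
          "type": "number"
        },
        "gamma": {
          "title": "Gamma",
          "type": "number"
        },
        "r_squared": {
          "title": "R Squared",
          "type": "number"
        }
      },
      "required": [
        "alpha",
        "beta",
        "gamma",
        "r_squared"
      ],
      "title": "TwoStateBlock",
      "type": "object"
    },
    "ValidationRow": {
      "properties": {
        "abs_error_pct": {
          "anyOf": [
            {
              "additionalProperties": {
                "type": "number"
              },
              "type": "object"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "Abs Error Pct"
        },
        "cell_line": {
          "title": "Cell Line",
          "type": "string"
        },
        "cem43_min": {
          "title": "Cem43 Min",
          "type": "number"
        },
        "predicted_survival_pct": {
          "additionalProperties": {
            "type": "number"
          },
          "title": "Predicted Survival Pct",
          "type": "object"
        },
        "profile_label": {
          "title": "Profile Label",
          "type": "string"
        },
        "reference_survival_pct": {
          "anyOf": [
            {
              "type": "number"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "Reference Survival Pct"
        }
      },
      "required": [
        "profile_label",
        "cell_line",
        "cem43_min",
        "predicted_survival_pct"
      ],
      "title": "ValidationRow",
      "type": "object"
    }
  },
  "properties": {
    "cell_lines": {
      "additionalProperties": {
        "$ref": "#/$defs/CellLineBlock"
      },
      "title": "Cell Lines",
      "type": "object"
    },
    "config": {
      "$ref": "#/$defs/AnalysisConfig"
    },
    "model_comparison": {
      "items": {
        "$ref": "#/$defs/ModelComparisonRow"
      },
      "title": "Model Comparison",
      "type": "array"
    },
    "validation": {
      "items": {
        "$ref": "#/$defs/ValidationRow"
      },
      "title": "Validation",
      "type": "array"
    }
  },
  "required": [
    "config",
    "cell_lines",
    "model_comparison"
  ],
  "title": "AnalysisReport",
  "type": "object"
}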