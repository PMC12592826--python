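{
  "properties": {
    "columns": {
      "items": {
        "type": "string"
      },
      "title": "Columns",
      "type": "array"
    },
    "coef": {
      "items": {
        "type": "number"
      },
      "title": "Coef",
      "type": "array"
    },
    "covariance": {
      "items": {
        "items": {
          "type": "number"
        },
        "type": "array"
      },
      "title": "Covariance",
      "type": "array"
    },
    "log_likelihood": {
      "title": "Log Likelihood",
      "type": "number"
    },
    "n_events": {
      "title": "N Events",
      "type": "integer"
    },
    "n_bins": {
      "title": "N Bins",
      "type": "integer"
    },
    "converged": {
      "title": "Converged",
      "type": "boolean"
    },
    "regularized": {
      "title": "Regularized",
      "type": "boolean"
    },
    "reliable": {
      "title": "Reliable",
      "type": "boolean"
    },
    "knots": {
      "items": {
        "type": "number"
      },
      "title": "Knots",
      "type": "array"
    },
    "tension": {
      "title": "Tension",
      "type": "number"
    },
    "bin_width": {
      "title": "Bin Width",
      "type": "number"
    },
    "burn_in_s": {
      "title": "Burn In S",
      "type": "number"
    },
    "stage_log_rates": {
      "additionalProperties": {
        "anyOf": [
          {
            "type": "number"
          },
          {
            "type": "null"
          }
        ]
      },
      "title": "Stage Log Rates",
      "type": "object"
    },
    "sdb_multiplier": {
      "anyOf": [
        {
          "type": "number"
        },
        {
          "type": "null"
        }
      ],
      "title": "Sdb Multiplier"
    },
    "arousal_multiplier": {
      "anyOf": [
        {
          "type": "number"
        },
        {
          "type": "null"
        }
      ],
      "title": "Arousal Multiplier"
    }
  },
  "required": [
    "columns",
    "coef",
    "covariance",
    "log_likelihood",
    "n_events",
    "n_bins",
    "converged",
    "regularized",
    "reliable",
    "knots",
    "tension",
    "bin_width",
    "burn_in_s",
    "stage_log_rates",
    "sdb_multiplier",
    "arousal_multiplier"
  ],
  "title": "FitJSON",
  "type": "object"
}
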