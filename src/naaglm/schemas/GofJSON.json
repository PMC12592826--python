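{
  "properties": {
    "ks_stat": {
      "anyOf": [
        {
          "type": "number"
        },
        {
          "type": "null"
        }
      ],
      "title": "Ks Stat"
    },
    "threshold": {
      "anyOf": [
        {
          "type": "number"
        },
        {
          "type": "null"
        }
      ],
      "title": "Threshold"
    },
    "n_events": {
      "title": "N Events",
      "type": "integer"
    },
    "passed": {
      "title": "Passed",
      "type": "boolean"
    },
    "alpha": {
      "default": 0.05,
      "title": "Alpha",
      "type": "number"
    }
  },
  "required": [
    "ks_stat",
    "threshold",
    "n_events",
    "passed"
  ],
  "title": "GofJSON",
  "type": "object"
}
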