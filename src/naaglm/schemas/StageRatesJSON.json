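{
  "properties": {
    "rates_per_hour": {
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
      "title": "Rates Per Hour",
      "type": "object"
    },
    "overall_per_hour": {
      "anyOf": [
        {
          "type": "number"
        },
        {
          "type": "null"
        }
      ],
      "title": "Overall Per Hour"
    }
  },
  "required": [
    "rates_per_hour",
    "overall_per_hour"
  ],
  "title": "StageRatesJSON",
  "type": "object"
}
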