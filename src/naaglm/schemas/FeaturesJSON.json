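{
  "properties": {
    "refractory_s": {
      "anyOf": [
        {
          "type": "number"
        },
        {
          "type": "null"
        }
      ],
      "title": "Refractory S"
    },
    "ip_duration_s": {
      "anyOf": [
        {
          "type": "number"
        },
        {
          "type": "null"
        }
      ],
      "title": "Ip Duration S"
    },
    "ip_peak_height": {
      "title": "Ip Peak Height",
      "type": "number"
    },
    "ip_peak_lag_s": {
      "title": "Ip Peak Lag S",
      "type": "number"
    },
    "ip_peak_width_s": {
      "title": "Ip Peak Width S",
      "type": "number"
    },
    "width_mode": {
      "default": "half_prominence",
      "title": "Width Mode",
      "type": "string"
    }
  },
  "required": [
    "refractory_s",
    "ip_duration_s",
    "ip_peak_height",
    "ip_peak_lag_s",
    "ip_peak_width_s"
  ],
  "title": "FeaturesJSON",
  "type": "object"
}
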