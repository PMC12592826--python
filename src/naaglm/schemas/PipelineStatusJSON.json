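{
  "properties": {
    "stages": {
      "additionalProperties": {
        "type": "string"
      },
      "description": "stage name -> ok/failed/skipped",
      "title": "Stages",
      "type": "object"
    },
    "messages": {
      "additionalProperties": {
        "type": "string"
      },
      "default": {},
      "title": "Messages",
      "type": "object"
    }
  },
  "required": [
    "stages"
  ],
  "title": "PipelineStatusJSON",
  "type": "object"
}
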