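{
  "description": "Resolved record of one CLI invocation.",
  "properties": {
    "tool": {
      "default": "rfclue",
      "title": "Tool",
      "type": "string"
    },
    "version": {
      "default": "0.1.0",
      "title": "Version",
      "type": "string"
    },
    "subcommand": {
      "title": "Subcommand",
      "type": "string"
    },
    "parameters": {
      "additionalProperties": true,
      "title": "Parameters",
      "type": "object"
    },
    "seed": {
      "anyOf": [
        {
          "type": "integer"
        },
        {
          "type": "null"
        }
      ],
      "default": null,
      "title": "Seed"
    },
    "input_checksums": {
      "additionalProperties": {
        "type": "string"
      },
      "title": "Input Checksums",
      "type": "object"
    },
    "artifacts": {
      "items": {
        "type": "string"
      },
      "title": "Artifacts",
      "type": "array"
    },
    "wall_clock_seconds": {
      "anyOf": [
        {
          "type": "number"
        },
        {
          "type": "null"
        }
      ],
      "default": null,
      "title": "Wall Clock Seconds"
    }
  },
  "required": [
    "subcommand",
    "parameters"
  ],
  "title": "RunManifest",
  "type": "object"
}
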