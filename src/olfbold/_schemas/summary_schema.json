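{
  "type": "object",
  "required": ["version", "seed", "alpha", "conditions", "paradigm", "roi_tables", "retest"],
  "properties": {
    "version": {"type": "string"},
    "seed": {"type": "integer"},
    "alpha": {"type": "number"},
    "paradigm": {
      "type": "object",
      "required": ["n_volumes", "n_blocks", "total_seconds", "pulses_per_block"],
      "properties": {
        "n_volumes": {"type": "integer"},
        "n_blocks": {"type": "integer"},
        "total_seconds": {"type": "number"},
        "pulses_per_block": {"type": "integer"}
      }
    },
    "conditions": {
      "type": "object"
    },
    "roi_tables": {
      "type": "object"
    },
    "cnr_comparison": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["roi", "n_voxels"]
      }
    },
    "retest": {
      "type": "object",
      "required": ["dice", "icc"],
      "properties": {
        "dice": {"type": "array"},
        "icc": {"type": "array"}
      }
    }
  }
}
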