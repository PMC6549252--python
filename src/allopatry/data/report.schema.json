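{
  "title": "allopatry pipeline report",
  "type": "object",
  "required": [
    "tool",
    "seed",
    "n_perm",
    "alternative",
    "inputs",
    "sites",
    "matrices",
    "mantel",
    "spearman",
    "clusters",
    "conventions",
    "warnings"
  ],
  "properties": {
    "tool": {"type": "object", "required": ["name", "version"]},
    "seed": {"type": ["integer", "null"]},
    "n_perm": {"type": "integer"},
    "alternative": {"type": "string"},
    "inputs": {"type": "object"},
    "sites": {
      "type": "object",
      "required": ["n", "with_coordinates", "without_coordinates", "plates"]
    },
    "matrices": {"type": "object"},
    "mantel": {"type": "object"},
    "spearman": {"type": "object"},
    "clusters": {"type": "object"},
    "classification": {"type": "array"},
    "conventions": {"type": "object"},
    "warnings": {"type": "array"}
  }
}
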