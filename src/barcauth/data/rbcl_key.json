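{
  "coordinate_name": "rbcLa-panel-v1",
  "positions": [66, 180, 263, 300, 372, 378, 492],
  "consensus": {"66": "C", "180": "C", "263": "A", "300": "A", "372": "A", "378": "A", "492": "A"},
  "core_types": [
    {"label": "1", "required_states": {"300": "G", "372": "C"}, "priority": 1},
    {"label": "2", "required_states": {"378": "G", "492": "T"}, "priority": 2}
  ],
  "marker_snps": {"66": "T", "263": "T"},
  "marker_label": "p",
  "intermediate_label": "1-2"
}
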