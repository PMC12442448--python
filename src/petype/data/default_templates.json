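[
  {
    "type_label": "I",
    "disulfide_count": 1,
    "disulfide_min": null,
    "disulfides_canonical": null,
    "extended_loop": false,
    "motif_in": null,
    "clamp": null,
    "loop3_delta_min": null,
    "scored_positions": {}
  },
  {
    "type_label": "IIa",
    "disulfide_count": 2,
    "disulfide_min": null,
    "disulfides_canonical": "all",
    "extended_loop": true,
    "motif_in": null,
    "clamp": null,
    "loop3_delta_min": null,
    "scored_positions": {}
  },
  {
    "type_label": "IIb",
    "disulfide_count": 2,
    "disulfide_min": null,
    "disulfides_canonical": "all",
    "extended_loop": true,
    "motif_in": null,
    "clamp": null,
    "loop3_delta_min": null,
    "scored_positions": {}
  },
  {
    "type_label": "III",
    "disulfide_count": null,
    "disulfide_min": 2,
    "disulfides_canonical": "none",
    "extended_loop": null,
    "motif_in": [
      "GHSQG"
    ],
    "clamp": false,
    "loop3_delta_min": 3,
    "scored_positions": {}
  }
]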