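{
  "_comment": [
    "Editable vendor rack presets. Vendors do not publish one canonical",
    "grid, so these are representative placeholder layouts: adjust the",
    "rows to the racks actually installed. Each row entry is taken in",
    "order as row A, B, C, ... with `n_tanks` tank slots of",
    "`spaces_per_tank` spaces each."
  ],
  "presets": {
    "Tecniplast": [
      {"n_tanks": 16, "spaces_per_tank": 1},
      {"n_tanks": 16, "spaces_per_tank": 1},
      {"n_tanks": 8, "spaces_per_tank": 2},
      {"n_tanks": 8, "spaces_per_tank": 2},
      {"n_tanks": 4, "spaces_per_tank": 4},
      {"n_tanks": 4, "spaces_per_tank": 4}
    ],
    "Aquaneering": [
      {"n_tanks": 14, "spaces_per_tank": 1},
      {"n_tanks": 14, "spaces_per_tank": 1},
      {"n_tanks": 7, "spaces_per_tank": 2},
      {"n_tanks": 7, "spaces_per_tank": 2},
      {"n_tanks": 7, "spaces_per_tank": 2}
    ],
    "Pentair": [
      {"n_tanks": 12, "spaces_per_tank": 1},
      {"n_tanks": 12, "spaces_per_tank": 1},
      {"n_tanks": 6, "spaces_per_tank": 2},
      {"n_tanks": 6, "spaces_per_tank": 2},
      {"n_tanks": 3, "spaces_per_tank": 4}
    ]
  }
}
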