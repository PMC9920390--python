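{
  "schema": "casepy-peaklist/1",
  "note": "Synthetic correlation table for 2-prop-2-enoyloxyethyl 2-hydroxybenzoate, hand-assembled from the known structure: 12 carbon signals, 5 oxygens with one hydroxyl proton, 14 HMBC and 4 COSY entries.",
  "mf": "C12H12O5",
  "c13": [
    {"id": "C1", "shift": 62.79, "kind": "signal"},
    {"id": "C2", "shift": 64.25, "kind": "signal"},
    {"id": "C3", "shift": 113.19, "kind": "signal", "multiplicity": 0},
    {"id": "C4", "shift": 118.34, "kind": "signal"},
    {"id": "C5", "shift": 119.61, "kind": "signal"},
    {"id": "C6", "shift": 128.21, "kind": "signal"},
    {"id": "C7", "shift": 130.12, "kind": "signal"},
    {"id": "C8", "shift": 131.28, "kind": "signal"},
    {"id": "C9", "shift": 135.9, "kind": "signal"},
    {"id": "C10", "shift": 161.45, "kind": "signal", "multiplicity": 0},
    {"id": "C11", "shift": 165.8, "kind": "signal", "multiplicity": 0},
    {"id": "C12", "shift": 166.3, "kind": "signal", "multiplicity": 0}
  ],
  "h1": [
    {"id": "H1", "shift": 4.49, "integral": 2.0},
    {"id": "H2", "shift": 4.42, "integral": 2.0},
    {"id": "H4", "shift": 6.95, "integral": 1.0},
    {"id": "H5", "shift": 6.88, "integral": 1.0},
    {"id": "H6", "shift": 6.15, "integral": 1.0},
    {"id": "H7", "shift": 7.45, "integral": 1.0},
    {"id": "H8a", "shift": 6.41, "integral": 1.0},
    {"id": "H8b", "shift": 5.86, "integral": 1.0},
    {"id": "H9", "shift": 7.84, "integral": 1.0},
    {"id": "H10", "shift": 10.81, "integral": 1.0}
  ],
  "hsqc": [
    {"proton": "H1", "carbon": "C1", "sign": "-"},
    {"proton": "H2", "carbon": "C2", "sign": "-"},
    {"proton": "H4", "carbon": "C4", "sign": "+", "protons": 1},
    {"proton": "H5", "carbon": "C5", "sign": "+", "protons": 1},
    {"proton": "H6", "carbon": "C6", "sign": "+", "protons": 1},
    {"proton": "H7", "carbon": "C7", "sign": "+", "protons": 1},
    {"proton": "H8a", "carbon": "C8", "sign": "-"},
    {"proton": "H8b", "carbon": "C8", "sign": "-"},
    {"proton": "H9", "carbon": "C9", "sign": "+", "protons": 1}
  ],
  "hmbc": [
    {"proton": "H1", "target": "C11"},
    {"proton": "H1", "target": "C2"},
    {"proton": "H2", "target": "C12"},
    {"proton": "H2", "target": "C1"},
    {"proton": "H4", "target": "C3"},
    {"proton": "H4", "target": "C5"},
    {"proton": "H4", "target": "C10"},
    {"proton": "H5", "target": "C3"},
    {"proton": "H5", "target": "C4"},
    {"proton": "H7", "target": "C10"},
    {"proton": "H9", "target": "C10"},
    {"proton": "H8a", "target": "C12"},
    {"proton": "H8b", "target": "C12"},
    {"proton": "H10", "target": "C3"}
  ],
  "cosy": [
    {"a": "H4", "b": "H9"},
    {"a": "H5", "b": "H9"},
    {"a": "H6", "b": "H8a"},
    {"a": "H6", "b": "H8b"}
  ],
  "hetero_attachments": [
    {"proton": "H10", "element": "O"}
  ]
}
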