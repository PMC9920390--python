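{
  "schema": "casepy-peaklist/1",
  "note": "Synthetic correlation table for N-phenylpropanamide, hand-assembled from the known structure; shifts follow the published assignment, 1H shifts and correlation selection are plausible stand-ins.",
  "mf": "C9H11NO",
  "c13": [
    {"id": "C3", "shift": 137.9, "kind": "signal", "multiplicity": 0},
    {"id": "C4", "shift": 30.8, "kind": "signal"},
    {"id": "C5", "shift": 172.2, "kind": "signal", "multiplicity": 0},
    {"id": "C6", "shift": 119.8, "kind": "signal"},
    {"id": "C7", "shift": 119.8, "kind": "signal"},
    {"id": "C8", "shift": 9.89, "kind": "signal"},
    {"id": "C9", "shift": 129.0, "kind": "signal"},
    {"id": "C10", "shift": 129.0, "kind": "signal"},
    {"id": "C11", "shift": 124.2, "kind": "signal"}
  ],
  "h1": [
    {"id": "H4", "shift": 2.35, "integral": 2.0},
    {"id": "H8", "shift": 1.21, "integral": 3.0},
    {"id": "H6", "shift": 7.55, "integral": 1.0},
    {"id": "H7", "shift": 7.55, "integral": 1.0},
    {"id": "H9", "shift": 7.3, "integral": 1.0},
    {"id": "H10", "shift": 7.3, "integral": 1.0},
    {"id": "H11", "shift": 7.08, "integral": 1.0},
    {"id": "HN", "shift": 9.82, "integral": 1.0}
  ],
  "hsqc": [
    {"proton": "H4", "carbon": "C4", "sign": "-"},
    {"proton": "H8", "carbon": "C8", "sign": "+", "protons": 3},
    {"proton": "H6", "carbon": "C6", "sign": "+", "protons": 1},
    {"proton": "H7", "carbon": "C7", "sign": "+", "protons": 1},
    {"proton": "H9", "carbon": "C9", "sign": "+", "protons": 1},
    {"proton": "H10", "carbon": "C10", "sign": "+", "protons": 1},
    {"proton": "H11", "carbon": "C11", "sign": "+", "protons": 1}
  ],
  "hmbc": [
    {"proton": "H8", "target": "C5"},
    {"proton": "H8", "target": "C4"},
    {"proton": "H4", "target": "C5"},
    {"proton": "H4", "target": "C8"},
    {"proton": "HN", "target": "C5"},
    {"proton": "HN", "target": "C3"},
    {"proton": "HN", "target": "C6"},
    {"proton": "HN", "target": "C7"},
    {"proton": "H6", "target": "C11"},
    {"proton": "H7", "target": "C11"},
    {"proton": "H9", "target": "C3"},
    {"proton": "H10", "target": "C3"},
    {"proton": "H11", "target": "C6"},
    {"proton": "H11", "target": "C7"}
  ],
  "cosy": [
    {"a": "H6", "b": "H9"},
    {"a": "H7", "b": "H10"},
    {"a": "H9", "b": "H11"},
    {"a": "H10", "b": "H11"}
  ],
  "hetero_attachments": [
    {"proton": "HN", "element": "N"}
  ]
}
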