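{
  "version": 1,
  "comment": "Monosaccharide templates with CHARMM-GUI style heavy-atom naming. Fragment atom order follows the canonical ring traversal (anomeric carbon first, increasing ring-carbon numbering, ring oxygen last).",
  "templates": {
    "GLC": {
      "ring_class": "pyranose",
      "anomeric_position": 1,
      "atoms": ["C1", "O1", "C2", "O2", "C3", "O3", "C4", "O4", "C5", "O5", "C6", "O6"],
      "bonds": [["C1", "C2"], ["C2", "C3"], ["C3", "C4"], ["C4", "C5"], ["C5", "O5"], ["O5", "C1"], ["C1", "O1"], ["C2", "O2"], ["C3", "O3"], ["C4", "O4"], ["C5", "C6"], ["C6", "O6"]],
      "ring": ["C1", "C2", "C3", "C4", "C5", "O5"],
      "anomeric_atom": "C1",
      "ring_ether_atom": "O5",
      "fragments": [["A", "hemiacetal", ["C1", "O1", "C2", "O2"]], ["B", "diol", ["C3", "O3", "C4", "O4"]], ["C", "ring_ether", ["C5", "C6", "O6", "O5"]]],
      "substituents": []
    },
    "GAL": {
      "ring_class": "pyranose",
      "anomeric_position": 1,
      "atoms": ["C1", "O1", "C2", "O2", "C3", "O3", "C4", "O4", "C5", "O5", "C6", "O6"],
      "bonds": [["C1", "C2"], ["C2", "C3"], ["C3", "C4"], ["C4", "C5"], ["C5", "O5"], ["O5", "C1"], ["C1", "O1"], ["C2", "O2"], ["C3", "O3"], ["C4", "O4"], ["C5", "C6"], ["C6", "O6"]],
      "ring": ["C1", "C2", "C3", "C4", "C5", "O5"],
      "anomeric_atom": "C1",
      "ring_ether_atom": "O5",
      "fragments": [["A", "hemiacetal", ["C1", "O1", "C2", "O2"]], ["B", "diol", ["C3", "O3", "C4", "O4"]], ["C", "ring_ether", ["C5", "C6", "O6", "O5"]]],
      "substituents": []
    },
    "MAN": {
      "ring_class": "pyranose",
      "anomeric_position": 1,
      "atoms": ["C1", "O1", "C2", "O2", "C3", "O3", "C4", "O4", "C5", "O5", "C6", "O6"],
      "bonds": [["C1", "C2"], ["C2", "C3"], ["C3", "C4"], ["C4", "C5"], ["C5", "O5"], ["O5", "C1"], ["C1", "O1"], ["C2", "O2"], ["C3", "O3"], ["C4", "O4"], ["C5", "C6"], ["C6", "O6"]],
      "ring": ["C1", "C2", "C3", "C4", "C5", "O5"],
      "anomeric_atom": "C1",
      "ring_ether_atom": "O5",
      "fragments": [["A", "hemiacetal", ["C1", "O1", "C2", "O2"]], ["B", "diol", ["C3", "O3", "C4", "O4"]], ["C", "ring_ether", ["C5", "C6", "O6", "O5"]]],
      "substituents": []
    },
    "XYL": {
      "ring_class": "pyranose",
      "anomeric_position": 1,
      "atoms": ["C1", "O1", "C2", "O2", "C3", "O3", "C4", "O4", "C5", "O5"],
      "bonds": [["C1", "C2"], ["C2", "C3"], ["C3", "C4"], ["C4", "C5"], ["C5", "O5"], ["O5", "C1"], ["C1", "O1"], ["C2", "O2"], ["C3", "O3"], ["C4", "O4"]],
      "ring": ["C1", "C2", "C3", "C4", "C5", "O5"],
      "anomeric_atom": "C1",
      "ring_ether_atom": "O5",
      "fragments": [["A", "hemiacetal", ["C1", "O1", "C2", "O2"]], ["B", "diol", ["C3", "O3", "C4", "O4"]], ["C", "ring_ether_tiny", ["C5", "O5"]]],
      "substituents": []
    },
    "LRHA": {
      "ring_class": "pyranose",
      "anomeric_position": 1,
      "atoms": ["C1", "O1", "C2", "O2", "C3", "O3", "C4", "O4", "C5", "O5", "C6"],
      "bonds": [["C1", "C2"], ["C2", "C3"], ["C3", "C4"], ["C4", "C5"], ["C5", "O5"], ["O5", "C1"], ["C1", "O1"], ["C2", "O2"], ["C3", "O3"], ["C4", "O4"], ["C5", "C6"]],
      "ring": ["C1", "C2", "C3", "C4", "C5", "O5"],
      "anomeric_atom": "C1",
      "ring_ether_atom": "O5",
      "fragments": [["A", "hemiacetal", ["C1", "O1", "C2", "O2"]], ["B", "diol", ["C3", "O3", "C4", "O4"]], ["C", "ring_ether_deoxy", ["C5", "C6", "O5"]]],
      "substituents": []
    },
    "LFUC": {
      "ring_class": "pyranose",
      "anomeric_position": 1,
      "atoms": ["C1", "O1", "C2", "O2", "C3", "O3", "C4", "O4", "C5", "O5", "C6"],
      "bonds": [["C1", "C2"], ["C2", "C3"], ["C3", "C4"], ["C4", "C5"], ["C5", "O5"], ["O5", "C1"], ["C1", "O1"], ["C2", "O2"], ["C3", "O3"], ["C4", "O4"], ["C5", "C6"]],
      "ring": ["C1", "C2", "C3", "C4", "C5", "O5"],
      "anomeric_atom": "C1",
      "ring_ether_atom": "O5",
      "fragments": [["A", "hemiacetal", ["C1", "O1", "C2", "O2"]], ["B", "diol", ["C3", "O3", "C4", "O4"]], ["C", "ring_ether_deoxy", ["C5", "C6", "O5"]]],
      "substituents": []
    },
    "FRUF": {
      "ring_class": "furanose",
      "anomeric_position": 2,
      "atoms": ["C1", "O1", "C2", "O2", "C3", "O3", "C4", "O4", "C5", "O5", "C6", "O6"],
      "bonds": [["C2", "C3"], ["C3", "C4"], ["C4", "C5"], ["C5", "O5"], ["O5", "C2"], ["C2", "O2"], ["C2", "C1"], ["C1", "O1"], ["C3", "O3"], ["C4", "O4"], ["C5", "C6"], ["C6", "O6"]],
      "ring": ["C2", "C3", "C4", "C5", "O5"],
      "anomeric_atom": "C2",
      "ring_ether_atom": "O5",
      "fragments": [["A", "hemiacetal", ["C2", "O2", "C1", "O1"]], ["B", "diol", ["C3", "O3", "C4", "O4"]], ["C", "ring_ether", ["C5", "C6", "O6", "O5"]]],
      "substituents": []
    },
    "RIBF": {
      "ring_class": "furanose",
      "anomeric_position": 1,
      "atoms": ["C1", "O1", "C2", "O2", "C3", "O3", "C4", "O4", "C5", "O5"],
      "bonds": [["C1", "C2"], ["C2", "C3"], ["C3", "C4"], ["C4", "O4"], ["O4", "C1"], ["C1", "O1"], ["C2", "O2"], ["C3", "O3"], ["C4", "C5"], ["C5", "O5"]],
      "ring": ["C1", "C2", "C3", "C4", "O4"],
      "anomeric_atom": "C1",
      "ring_ether_atom": "O4",
      "fragments": [["A", "hemiacetal", ["C1", "O1", "C2", "O2"]], ["B", "hydroxyl", ["C3", "O3"]], ["C", "ring_ether", ["C4", "C5", "O5", "O4"]]],
      "substituents": []
    },
    "GLCA": {
      "ring_class": "pyranose",
      "anomeric_position": 1,
      "atoms": ["C1", "O1", "C2", "O2", "C3", "O3", "C4", "O4", "C5", "O5", "C6", "O61", "O62"],
      "bonds": [["C1", "C2"], ["C2", "C3"], ["C3", "C4"], ["C4", "C5"], ["C5", "O5"], ["O5", "C1"], ["C1", "O1"], ["C2", "O2"], ["C3", "O3"], ["C4", "O4"], ["C5", "C6"], ["C6", "O61"], ["C6", "O62"]],
      "ring": ["C1", "C2", "C3", "C4", "C5", "O5"],
      "anomeric_atom": "C1",
      "ring_ether_atom": "O5",
      "fragments": [["A", "hemiacetal", ["C1", "O1", "C2", "O2"]], ["B", "diol", ["C3", "O3", "C4", "O4"]], ["C", "ring_ether_tiny", ["C5", "O5"]], ["D", "acid", ["C6", "O61", "O62"]]],
      "substituents": [{"atoms": ["C6", "O61", "O62"], "separate": true}]
    },
    "INOSITOL": {
      "ring_class": "pyranose",
      "anomeric_position": 1,
      "atoms": ["C1", "O1", "C2", "O2", "C3", "O3", "C4", "O4", "C5", "O5", "C6", "O6"],
      "bonds": [["C1", "C2"], ["C2", "C3"], ["C3", "C4"], ["C4", "C5"], ["C5", "C6"], ["C6", "C1"], ["C1", "O1"], ["C2", "O2"], ["C3", "O3"], ["C4", "O4"], ["C5", "O5"], ["C6", "O6"]],
      "ring": ["C1", "C2", "C3", "C4", "C5", "C6"],
      "anomeric_atom": "C1",
      "ring_ether_atom": null,
      "fragments": [["A", "diol", ["C1", "O1", "C2", "O2"]], ["B", "diol", ["C3", "O3", "C4", "O4"]], ["C", "diol", ["C5", "O5", "C6", "O6"]]],
      "substituents": []
    },
    "NEU5AC": {
      "ring_class": "pyranose",
      "anomeric_position": 2,
      "atoms": ["C1", "O1A", "O1B", "C2", "O2", "C3", "C4", "O4", "C5", "N5", "C10", "O10", "C11", "C6", "O6", "C7", "O7", "C8", "O8", "C9", "O9"],
      "bonds": [["C2", "C3"], ["C3", "C4"], ["C4", "C5"], ["C5", "C6"], ["C6", "O6"], ["O6", "C2"], ["C2", "O2"], ["C2", "C1"], ["C1", "O1A"], ["C1", "O1B"], ["C4", "O4"], ["C5", "N5"], ["N5", "C10"], ["C10", "O10"], ["C10", "C11"], ["C6", "C7"], ["C7", "O7"], ["C7", "C8"], ["C8", "O8"], ["C8", "C9"], ["C9", "O9"]],
      "ring": ["C2", "C3", "C4", "C5", "C6", "O6"],
      "anomeric_atom": "C2",
      "ring_ether_atom": "O6",
      "fragments": [["A", "acid_anomeric", ["C2", "O2", "C1", "O1A", "O1B"]], ["B", "ring_monoalcohol", ["C3", "C4", "O4", "C5"]], ["C", "ring_ether_tiny", ["C6", "O6"]], ["D", "acetamide", ["N5", "C10", "O10", "C11"]], ["E", "diol", ["C7", "O7", "C8", "O8"]], ["F", "hydroxyl", ["C9", "O9"]]],
      "substituents": [{"atoms": ["C1", "O1A", "O1B"], "separate": false}, {"atoms": ["N5", "C10", "O10", "C11"], "separate": true}, {"atoms": ["C7", "O7", "C8", "O8"], "separate": true}, {"atoms": ["C9", "O9"], "separate": true}]
    }
  }
}
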