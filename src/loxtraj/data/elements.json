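{
  "comment": "Standard atomic masses (Da) and van der Waals radii (A, Bondi 1964 where defined). FE radius is the common 2.0 A working value for structural grids.",
  "default": {"mass": 12.0, "vdw_radius": 1.7},
  "elements": {
    "H":  {"mass": 1.008,  "vdw_radius": 1.20},
    "C":  {"mass": 12.011, "vdw_radius": 1.70},
    "N":  {"mass": 14.007, "vdw_radius": 1.55},
    "O":  {"mass": 15.999, "vdw_radius": 1.52},
    "P":  {"mass": 30.974, "vdw_radius": 1.80},
    "S":  {"mass": 32.06,  "vdw_radius": 1.80},
    "F":  {"mass": 18.998, "vdw_radius": 1.47},
    "CL": {"mass": 35.45,  "vdw_radius": 1.75},
    "BR": {"mass": 79.904, "vdw_radius": 1.85},
    "I":  {"mass": 126.904,"vdw_radius": 1.98},
    "NA": {"mass": 22.990, "vdw_radius": 2.27},
    "K":  {"mass": 39.098, "vdw_radius": 2.75},
    "MG": {"mass": 24.305, "vdw_radius": 1.73},
    "CA": {"mass": 40.078, "vdw_radius": 2.31},
    "ZN": {"mass": 65.38,  "vdw_radius": 1.39},
    "FE": {"mass": 55.845, "vdw_radius": 2.00},
    "SE": {"mass": 78.971, "vdw_radius": 1.90}
  }
}
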