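{
  "_comment": [
    "Editable reference table of molecular fragment volumes and coherent",
    "scattering lengths used to parametrise the floating-bilayer model.",
    "Volumes in cubic angstrom per molecule; sumb_h is the summed coherent",
    "scattering length (fm) of the fully protonated fragment; labile_h is",
    "the number of solvent-exchangeable hydrogens.  Values are standard",
    "literature figures for lipid fragment volumes/compositions and simple",
    "atomic-b sums; they are configuration, not code, and may be edited."
  ],
  "fragments": {
    "POPC_head":   {"volume": 319.0, "sumb_h": 60.1,  "labile_h": 0},
    "POPC_tail":   {"volume": 937.0, "sumb_h": -26.6, "labile_h": 0},
    "POPS_head":   {"volume": 278.0, "sumb_h": 84.6,  "labile_h": 3},
    "POPS_tail":   {"volume": 937.0, "sumb_h": -26.6, "labile_h": 0},
    "DOPIP3_head": {"volume": 500.0, "sumb_h": 144.0, "labile_h": 5},
    "DOPIP3_tail": {"volume": 984.0, "sumb_h": -20.8, "labile_h": 0},
    "CHOL":        {"volume": 630.0, "sumb_h": 13.2,  "labile_h": 1},
    "DGDG_head":   {"volume": 480.0, "sumb_h": 89.5,  "labile_h": 7},
    "DGDG_tail":   {"volume": 900.0, "sumb_h": -30.0, "labile_h": 0},
    "SAM":         {"volume": 460.0, "sumb_h": 24.0,  "labile_h": 1}
  },
  "lipids": {
    "POPC":   {"head": "POPC_head",   "tail": "POPC_tail"},
    "POPS":   {"head": "POPS_head",   "tail": "POPS_tail"},
    "DOPIP3": {"head": "DOPIP3_head", "tail": "DOPIP3_tail"},
    "CHOL":   {"head": null,          "tail": "CHOL"},
    "DGDG":   {"head": "DGDG_head",   "tail": "DGDG_tail"}
  },
  "solvent_sld": {"D2O": 6.35, "H2O": -0.56},
  "water_volume": 30.0,
  "b_exchange_per_h": 10.41,
  "substrate_sld": {
    "Si": 2.07, "SiO2": 3.47, "permalloy": 9.1, "gold": 4.66
  }
}
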