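{
  "elements": {
    "H":  {"Z": 1,  "A": 1.008},
    "C":  {"Z": 6,  "A": 12.011},
    "N":  {"Z": 7,  "A": 14.007},
    "O":  {"Z": 8,  "A": 15.999},
    "Al": {"Z": 13, "A": 26.982},
    "Au": {"Z": 79, "A": 196.967}
  },
  "materials": {
    "water": {
      "density_g_cm3": 1.0,
      "mean_excitation_energy_eV": 78.0,
      "composition": {"H": 0.1119, "O": 0.8881}
    },
    "soft_tissue": {
      "density_g_cm3": 1.0,
      "mean_excitation_energy_eV": 72.0,
      "composition": {"H": 0.101172, "C": 0.111, "N": 0.026, "O": 0.761828}
    },
    "gold": {
      "density_g_cm3": 19.32,
      "mean_excitation_energy_eV": 790.0,
      "composition": {"Au": 1.0}
    },
    "aluminum": {
      "density_g_cm3": 2.699,
      "mean_excitation_energy_eV": 166.0,
      "composition": {"Al": 1.0}
    }
  }
}
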