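{
  "comment": "Effective single-level-per-shell relaxation data. Binding energies in eV; fluorescence yields are shell-averaged standard values. A vacancy in shell i either emits a characteristic photon of energy B_i - B_next (probability = fluorescence yield, vacancy moves outward) or an Auger electron of energy B_i - 2*B_next (two vacancies in the next shell). Shells with binding below 100 eV relax by local deposition.",
  "Au": {
    "shells": ["K", "L", "M", "N"],
    "binding_eV": {"K": 80725.0, "L": 13000.0, "M": 2700.0, "N": 450.0},
    "fluorescence_yield": {"K": 0.96, "L": 0.34, "M": 0.02, "N": 0.0},
    "photoionization_fractions": {
      "above_K": {"K": 0.80, "L": 0.15, "M": 0.04, "N": 0.01},
      "above_L": {"L": 0.78, "M": 0.17, "N": 0.05},
      "above_M": {"M": 0.85, "N": 0.15},
      "below_M": {"N": 1.0}
    }
  },
  "O": {
    "shells": ["K"],
    "binding_eV": {"K": 543.0},
    "fluorescence_yield": {"K": 0.008},
    "photoionization_fractions": {"above_K": {"K": 1.0}}
  }
}
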