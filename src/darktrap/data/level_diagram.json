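{
  "comment": "Level diagram of the meta-HBDI anion and its neutral radical. Energies in eV relative to the anion S0 minimum; thresholds carry measured/calculated provenance. meci entries are barrier heights in eV above the S1 minimum.",
  "states": [
    {"label": "S0", "species": "anion", "adiabatic_energy": 0.0},
    {"label": "S1", "species": "anion", "adiabatic_energy": 1.51, "vertical_energy": 1.76, "oscillator_strength_from_S0": 0.03},
    {"label": "S2", "species": "anion", "vertical_energy": 3.2, "oscillator_strength_from_S0": 0.7},
    {"label": "S6", "species": "anion", "vertical_energy": 4.6},
    {"label": "D0", "species": "neutral", "adiabatic_energy": 2.30, "vertical_energy": 2.63},
    {"label": "D1n", "species": "neutral", "vertical_energy": 3.67}
  ],
  "vde_d0": {
    "measured": {"value_eV": 2.63, "provenance": "measured"},
    "calculated": {"value_eV": 2.54, "provenance": "calculated"}
  },
  "ade_d0": {
    "measured": {"value_eV": 2.30, "provenance": "measured"}
  },
  "vde_d1n": {
    "calculated": {"value_eV": 3.58, "provenance": "calculated"}
  },
  "meci": {
    "s1_s0": 0.41,
    "s2_s0": 0.55
  }
}
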