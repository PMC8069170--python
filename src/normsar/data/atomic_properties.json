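{
  "_comment": "Frozen atomic reference values: SN = period (electron shell number), EN = Pauling electronegativity (dimensionless), Ei = first ionization energy (eV, NIST), hardness = chemical hardness eta (eV, Pearson) used only by the charge-equalization scheme, covalent_radius in Angstrom (Cordero 2008) used only for bond perception.",
  "version": 1,
  "elements": {
    "H":  {"SN": 1, "EN": 2.20, "Ei": 13.598, "hardness": 6.42, "covalent_radius": 0.31, "valence": 1},
    "C":  {"SN": 2, "EN": 2.55, "Ei": 11.260, "hardness": 5.00, "covalent_radius": 0.76, "valence": 4},
    "N":  {"SN": 2, "EN": 3.04, "Ei": 14.534, "hardness": 7.23, "covalent_radius": 0.71, "valence": 3},
    "O":  {"SN": 2, "EN": 3.44, "Ei": 13.618, "hardness": 6.08, "covalent_radius": 0.66, "valence": 2},
    "S":  {"SN": 3, "EN": 2.58, "Ei": 10.360, "hardness": 4.14, "covalent_radius": 1.05, "valence": 2},
    "P":  {"SN": 3, "EN": 2.19, "Ei": 10.487, "hardness": 4.88, "covalent_radius": 1.07, "valence": 3},
    "F":  {"SN": 2, "EN": 3.98, "Ei": 17.423, "hardness": 7.01, "covalent_radius": 0.57, "valence": 1},
    "Cl": {"SN": 3, "EN": 3.16, "Ei": 12.968, "hardness": 4.68, "covalent_radius": 1.02, "valence": 1},
    "Br": {"SN": 4, "EN": 2.96, "Ei": 11.814, "hardness": 4.22, "covalent_radius": 1.20, "valence": 1},
    "I":  {"SN": 5, "EN": 2.66, "Ei": 10.451, "hardness": 3.69, "covalent_radius": 1.39, "valence": 1},
    "Fe": {"SN": 4, "EN": 1.83, "Ei": 7.902,  "hardness": 3.81, "covalent_radius": 1.32, "valence": 3}
  }
}
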