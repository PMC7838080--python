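{
  "comment": "Acyl-acceptor pocket residues, catalytic histidines and CoA-site residues of the two spermidine acyltransferases AtSHT (AT2G23510, PDB 6LPV) and AtSDT (AT2G19070, PDB 6LPW), transcribed from the published structural descriptions. Positions are one-letter residue code + PDB residue number. Role tags: h-bond = direct hydrogen bond to the acceptor, water-mediated = hydrogen bond through an ordered water, vdw = van der Waals contact, catalytic = general base.",
  "AtSHT": {
    "gene": "AT2G23510",
    "pdb": "6LPV",
    "acceptor_class": "polyamine/amine acceptor",
    "catalytic_his": "H155",
    "acceptor_pocket": [
      {"position": "T33", "role": "h-bond"},
      {"position": "I37", "role": "vdw"},
      {"position": "G290", "role": "vdw"},
      {"position": "C292", "role": "vdw"},
      {"position": "T312", "role": "vdw"},
      {"position": "D314", "role": "h-bond"},
      {"position": "V386", "role": "vdw"},
      {"position": "H411", "role": "water-mediated"},
      {"position": "D416", "role": "water-mediated"}
    ]
  },
  "AtSDT": {
    "gene": "AT2G19070",
    "pdb": "6LPW",
    "acceptor_class": "polyamine/amine acceptor",
    "catalytic_his": "H169",
    "acceptor_pocket": [
      {"position": "D40", "role": "vdw"},
      {"position": "N43", "role": "vdw"},
      {"position": "Y47", "role": "water-mediated"},
      {"position": "G292", "role": "vdw"},
      {"position": "S294", "role": "h-bond"},
      {"position": "Y314", "role": "vdw"},
      {"position": "D316", "role": "h-bond"},
      {"position": "Y318", "role": "vdw"},
      {"position": "E354", "role": "vdw"},
      {"position": "T358", "role": "vdw"},
      {"position": "C377", "role": "vdw"},
      {"position": "T379", "role": "water-mediated"},
      {"position": "W381", "role": "water-mediated"}
    ]
  },
  "coa_site": ["R246", "R263", "S387", "T390", "E265", "T262", "R298"],
  "labels": {
    "AtSHT": "polyamine/amine acceptor",
    "AtSDT": "polyamine/amine acceptor",
    "AtSCT": "polyamine/amine acceptor",
    "AtHCT": "shikimate-type acceptor"
  }
}
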