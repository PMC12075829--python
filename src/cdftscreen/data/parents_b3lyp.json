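[
 {
  "name": "genistein",
  "theory": "B3LYP/6-31G",
  "energies": {
   "neutral": -25945.0554146,
   "anion": null,
   "cation": null,
   "homo": null,
   "lumo": null,
   "unit": "eV"
  },
  "thermo": null,
  "dipole": null,
  "smiles": "C1=CC(=CC=C1C2=COC3=CC(=CC(=C3C2=O)O)O)O"
 },
 {
  "name": "hyoscyamine",
  "theory": "B3LYP/6-31G",
  "energies": {
   "neutral": -25627.88899259,
   "anion": null,
   "cation": null,
   "homo": null,
   "lumo": null,
   "unit": "eV"
  },
  "thermo": null,
  "dipole": null,
  "smiles": "CN1[C@@H]2CC[C@H]1C[C@H](C2)OC(=O)[C@@H](CO)c1ccccc1"
 }
]
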