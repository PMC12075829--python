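[
 {
  "name": "genistein",
  "theory": "APFD/6-311++G(d,p)",
  "energies": {
   "neutral": -25932.451092426563,
   "anion": -25932.80109242656,
   "cation": -25924.831092426564,
   "homo": -6.24,
   "lumo": -1.82,
   "unit": "eV"
  },
  "thermo": null,
  "dipole": null,
  "smiles": "C1=CC(=CC=C1C2=COC3=CC(=CC(=C3C2=O)O)O)O"
 },
 {
  "name": "hyoscyamine",
  "theory": "APFD/6-311++G(d,p)",
  "energies": {
   "neutral": -25633.125843720696,
   "anion": -25632.775843720698,
   "cation": -25625.195843720696,
   "homo": -6.26,
   "lumo": -0.57,
   "unit": "eV"
  },
  "thermo": null,
  "dipole": null,
  "smiles": "CN1[C@@H]2CC[C@H]1C[C@H](C2)OC(=O)[C@@H](CO)c1ccccc1"
 }
]
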