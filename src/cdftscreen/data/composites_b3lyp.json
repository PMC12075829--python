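[
 {
  "name": "composite_01",
  "theory": "B3LYP/6-31G",
  "energies": {
   "neutral": -51573.566132884,
   "anion": null,
   "cation": null,
   "homo": -5.494794765,
   "lumo": -1.700167271,
   "unit": "eV"
  },
  "thermo": {
   "zpe": 16.503105728,
   "enthalpy": 17.517219586,
   "free_energy": 14.4533266,
   "heat_capacity": 141.575,
   "entropy": 236.977,
   "temperature": 298.15
  },
  "dipole": 5.183797,
  "smiles": null
 },
 {
  "name": "composite_02",
  "theory": "B3LYP/6-31G",
  "energies": {
   "neutral": -51573.561316469,
   "anion": null,
   "cation": null,
   "homo": -5.616973879,
   "lumo": -1.548055634,
   "unit": "eV"
  },
  "thermo": {
   "zpe": 16.503677167,
   "enthalpy": 17.515342,
   "free_energy": 14.483204696,
   "heat_capacity": 141.47,
   "entropy": 234.521,
   "temperature": 298.15
  },
  "dipole": 5.998336,
  "smiles": null
 },
 {
  "name": "composite_03",
  "theory": "B3LYP/6-31G",
  "energies": {
   "neutral": -51573.364550951,
   "anion": null,
   "cation": null,
   "homo": -5.66731494,
   "lumo": -1.565743034,
   "unit": "eV"
  },
  "thermo": {
   "zpe": 16.479894418,
   "enthalpy": 17.501899577,
   "free_energy": 14.40581552,
   "heat_capacity": 142.205,
   "entropy": 239.468,
   "temperature": 298.15
  },
  "dipole": 4.686252,
  "smiles": null
 },
 {
  "name": "composite_04",
  "theory": "B3LYP/6-31G",
  "energies": {
   "neutral": -51573.605834293,
   "anion": null,
   "cation": null,
   "homo": -5.321458249,
   "lumo": -1.737446867,
   "unit": "eV"
  },
  "thermo": {
   "zpe": 16.506915322,
   "enthalpy": 17.513437204,
   "free_energy": 14.524756479,
   "heat_capacity": 141.373,
   "entropy": 231.163,
   "temperature": 298.15
  },
  "dipole": 3.811547,
  "smiles": null
 },
 {
  "name": "composite_05",
  "theory": "B3LYP/6-31G",
  "energies": {
   "neutral": -51573.69209438,
   "anion": null,
   "cation": null,
   "homo": -5.430303785,
   "lumo": -1.579348726,
   "unit": "eV"
  },
  "thermo": {
   "zpe": 16.513037883,
   "enthalpy": 17.518825058,
   "free_energy": 14.521164577,
   "heat_capacity": 141.157,
   "entropy": 231.856,
   "temperature": 298.15
  },
  "dipole": 4.843281,
  "smiles": null
 },
 {
  "name": "composite_06",
  "theory": "B3LYP/6-31G",
  "energies": {
   "neutral": -51573.258181651,
   "anion": null,
   "cation": null,
   "homo": -5.498060131,
   "lumo": -1.438121643,
   "unit": "eV"
  },
  "thermo": {
   "zpe": 16.473526954,
   "enthalpy": 17.497845081,
   "free_energy": 14.411829236,
   "heat_capacity": 142.545,
   "entropy": 238.689,
   "temperature": 298.15
  },
  "dipole": 5.374763,
  "smiles": null
 }
]
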