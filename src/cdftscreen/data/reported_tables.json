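{
 "global_indices": {
  "genistein": {
   "e_n_ha": -953,
   "e_anion_ha": -953,
   "e_cation_ha": -953,
   "homo": -6.24,
   "lumo": -1.82,
   "gap": 4.42,
   "ip": 7.62,
   "ea": 0.35,
   "electronegativity": 3.98,
   "chemical_potential": -3.98,
   "hardness": 7.28,
   "softness": 0.14,
   "electrophilicity": 1.09,
   "nucleophilicity": 0.92
  },
  "hyoscyamine": {
   "e_n_ha": -942,
   "e_anion_ha": -942,
   "e_cation_ha": -941,
   "homo": -6.26,
   "lumo": -0.57,
   "gap": 5.69,
   "ip": 7.93,
   "ea": -0.35,
   "electronegativity": 3.79,
   "chemical_potential": -3.79,
   "hardness": 8.28,
   "softness": 0.12,
   "electrophilicity": 0.86,
   "nucleophilicity": 1.16
  }
 },
 "band_gap": {
  "01": 3.794627494,
  "02": 4.068918245,
  "03": 4.101571906,
  "04": 3.584011382,
  "05": 3.850955059,
  "06": 4.059938488
 },
 "binding_energy": {
  "01": -0.621725694,
  "02": -0.616909279,
  "03": -0.420143761,
  "04": -0.661427102998,
  "05": -0.74768719,
  "06": -0.313774460999
 }
}
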