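{
 "entries": [
  {
   "name": "Cotinine",
   "formula": "C10H12N2O",
   "adduct": "[M+H]+",
   "mz": 177.1023,
   "rt": 60.0,
   "mode": "hilic_pos"
  },
  {
   "name": "Hydroxycotinine",
   "formula": "C10H12N2O2",
   "adduct": "[M+H]+",
   "mz": 193.0973,
   "rt": 75.0,
   "mode": "hilic_pos"
  },
  {
   "name": "Alanine",
   "formula": "C3H7NO2",
   "adduct": "[M+H]+",
   "mz": 90.055,
   "rt": 52.4,
   "mode": "hilic_pos"
  },
  {
   "name": "1-Aminocyclopropane-1-carboxylate",
   "formula": "C4H7NO2",
   "adduct": "[M+H]+",
   "mz": 102.055,
   "rt": 66.2,
   "mode": "hilic_pos"
  },
  {
   "name": "Maleamate",
   "formula": "C4H5NO3",
   "adduct": "[M+H]+",
   "mz": 116.0344,
   "rt": 78.1,
   "mode": "hilic_pos"
  },
  {
   "name": "Creatine",
   "formula": "C4H9N3O2",
   "adduct": "[M+H]+",
   "mz": 132.0766,
   "rt": 53.7,
   "mode": "hilic_pos"
  },
  {
   "name": "Guanidinobutanoate",
   "formula": "C5H11N3O2",
   "adduct": "[M+H]+",
   "mz": 146.0924,
   "rt": 25.7,
   "mode": "hilic_pos"
  },
  {
   "name": "Acetylcholine",
   "formula": "C7H15NO2",
   "adduct": "[M+H]+",
   "mz": 146.1176,
   "rt": 36.4,
   "mode": "hilic_pos"
  },
  {
   "name": "Hippurate",
   "formula": "C9H9NO3",
   "adduct": "[M+H]+",
   "mz": 180.0653,
   "rt": 44.2,
   "mode": "hilic_pos"
  },
  {
   "name": "Kynurenine",
   "formula": "C10H12N2O3",
   "adduct": "[M+H]+",
   "mz": 209.092,
   "rt": 251.0,
   "mode": "hilic_pos"
  },
  {
   "name": "Cystine",
   "formula": "C6H12N2O4S2",
   "adduct": "[M+H]+",
   "mz": 241.0308,
   "rt": 183.1,
   "mode": "hilic_pos"
  },
  {
   "name": "Vitamin A (Retinol)",
   "formula": "C20H30O",
   "adduct": "[M+H-H2O]+",
   "mz": 269.2263,
   "rt": 22.4,
   "mode": "hilic_pos"
  },
  {
   "name": "Itaconate",
   "formula": "C5H6O4",
   "adduct": "[M-H]-",
   "mz": 129.0187,
   "rt": 22.6,
   "mode": "c18_neg"
  },
  {
   "name": "L-Tyrosine",
   "formula": "C9H11NO3",
   "adduct": "[M-H]-",
   "mz": 180.0667,
   "rt": 19.6,
   "mode": "c18_neg"
  },
  {
   "name": "N-Acetyl-Glutamic Acid",
   "formula": "C7H11NO5",
   "adduct": "[M-H]-",
   "mz": 188.0566,
   "rt": 17.8,
   "mode": "c18_neg"
  },
  {
   "name": "Gluconic Acid",
   "formula": "C6H12O7",
   "adduct": "[M-H]-",
   "mz": 195.0512,
   "rt": 18.8,
   "mode": "c18_neg"
  },
  {
   "name": "FA 20:1 (Gondoic acid)",
   "formula": "C20H38O2",
   "adduct": "[M-H]-",
   "mz": 309.2803,
   "rt": 291.2,
   "mode": "c18_neg"
  },
  {
   "name": "Arachidic Acid",
   "formula": "C20H40O2",
   "adduct": "[M-H]-",
   "mz": 311.296,
   "rt": 291.3,
   "mode": "c18_neg"
  },
  {
   "name": "Adenosine-5'-Diphosphoglucose",
   "formula": "C16H25N5O15P2",
   "adduct": "[M-H]-",
   "mz": 588.076,
   "rt": 17.2,
   "mode": "c18_neg"
  }
 ]
}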