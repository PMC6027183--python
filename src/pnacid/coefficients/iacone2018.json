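{
  "name": "iacone2018",
  "ta": {
    "intercept": 0.769,
    "glucose": -0.029,
    "lipid": 0.619,
    "amino_acid": 1.001,
    "calcium": 0.078,
    "phosphorus": 0.487,
    "sodium": -0.004,
    "potassium": 0.002,
    "magnesium": -0.070
  },
  "ph": {
    "intercept": 5.894,
    "glucose": -0.007,
    "lipid": 0.026,
    "amino_acid": 0.050,
    "calcium": 0.009,
    "phosphorus": -0.036,
    "sodium": -0.001,
    "potassium": 0.0003,
    "magnesium": -0.003
  },
  "provenance": "Published multiple-regression coefficients from 50 titrated adult PN admixtures compounded from a single product line (10% amino acid, 50% glucose, 20% lipid emulsion, calcium gluconate, fructose-1,6-diphosphate, NaCl, KCl, MgSO4); TA fit r = 0.998, pH fit r = 0.959."
}
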