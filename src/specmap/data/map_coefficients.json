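{
  "description": "Published multilinear-regression spectroscopic-map coefficients for the terminal-alkyne CC stretch shift due to triethylamine, with gas-phase frequencies and the QM1->QMinf finite-QM-region corrections for the two probe solutes.",
  "coefficients": {
    "a0": -151.0,
    "a1": 1960.0,
    "a2": -1060.0,
    "b_H": 378.0,
    "b_CH": 300.0,
    "b_CR": -1490.0
  },
  "coefficient_units": {
    "a0": "cm^-1 per E_h/(e a0)",
    "a1": "cm^-1 per E_h/(e a0^2)",
    "a2": "cm^-1 per E_h/(e a0^3)",
    "b_H": "cm^-1 per E_h",
    "b_CH": "cm^-1 per E_h",
    "b_CR": "cm^-1 per E_h"
  },
  "omega_gas": {
    "PAC": 2138.39,
    "EBA": 2110.65
  },
  "qm_correction": {
    "PAC": 3.3,
    "EBA": 4.0
  },
  "notes": "PAC = propargyl acetate, EBA = 4-ethynylbenzyl alcohol. The last printed digit of each coefficient is uncertain (95% CI of the mean over 25 random 3/4 training-set refits)."
}
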