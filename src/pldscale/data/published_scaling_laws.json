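{
  "version": "1.0",
  "note": "Scaling constants for critical-temperature shifts of PLD condensates per mutation class, as fitted on the 140-variant direct-coexistence dataset. S is in K per unit of the ansatz variable x: x = N (count), x = N/L (fraction), or x = N/sqrt(L) (sqrt). Sign convention: delta_Tc = Tc(variant) - Tc(wild type).",
  "laws": [
    {"pair": "Y->F", "ansatz": "count", "S": -0.40, "S_err": 0.04, "r_squared": 0.88,
     "note": "Tyr to Phe; per-substitution shift, length-independent"},
    {"pair": "F/Y->W", "ansatz": "count", "S": 4.3, "S_err": 0.1, "r_squared": 0.99,
     "note": "Phe or Tyr to Trp; per-substitution shift, length-independent"},
    {"pair": "F/Y->X", "ansatz": "sqrt", "S": -56.0, "S_err": 5.0, "r_squared": null,
     "note": "aromatic deletion to uncharged non-aromatic, screened by sqrt(L)"},
    {"pair": "R->K", "ansatz": "fraction", "S": -1300.0, "S_err": 100.0, "r_squared": 0.94,
     "note": "Arg to Lys; per unit mutation fraction"},
    {"pair": "R->X", "ansatz": "fraction", "S": -640.0, "S_err": 50.0, "r_squared": 0.96,
     "note": "Arg deletion to uncharged non-aromatic; per unit mutation fraction"},
    {"pair": "N->Q", "ansatz": "fraction", "S": 50.0, "S_err": 5.0, "r_squared": 0.84,
     "note": "Asn to Gln; per unit mutation fraction"},
    {"pair": "S->T", "ansatz": "count", "S": -0.09, "S_err": 0.03, "r_squared": 0.70,
     "note": "Ser to Thr; per-substitution shift"},
    {"pair": "G->T", "ansatz": "count", "S": -0.08, "S_err": 0.02, "r_squared": 0.70,
     "note": "Gly to Thr; per-substitution shift"},
    {"pair": "A->S", "ansatz": "count", "S": 0.16, "S_err": 0.05, "r_squared": 0.77,
     "note": "Ala to Ser; per-substitution shift"},
    {"pair": "G->S", "ansatz": null, "S": null, "S_err": null, "r_squared": null,
     "note": "Gly to Ser: reported only as a very minor decrease, no constant fitted; predictions refuse this pair"}
  ]
}
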