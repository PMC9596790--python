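{
 "_meta": {
  "description": "Active atrial fibroblast baseline (MacCannell/Maleckar four-current formulation). Conductances in nS (per-cell, Cm = 6.3 pF), pump maximum in pA, concentrations mM.",
  "version": "1.0"
 },
 "g_kv": 1.575,
 "g_k1": 3.0379,
 "i_nak_max": 12.613,
 "g_nab": 0.0643,
 "k_o": 5.3,
 "na_o": 130.0,
 "cm": 6.3,
 "na_i": 8.5547,
 "k_i": 129.4349
}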