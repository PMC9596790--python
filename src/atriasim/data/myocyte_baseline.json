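{
 "_meta": {
  "description": "AF-remodelled human atrial myocyte baseline (Nygren/Koivumaki family). Units: p_na nL/s; conductances nS; pump/exchanger maxima pA (k_naca pA/mM^4); concentrations mM; cm pF; diffusion cm^2/ms.",
  "version": "1.0",
  "diffusion": 0.0016
 },
 "p_na": 0.004,
 "g_cal": 2.7675,
 "g_t": 2.85,
 "g_kur": 0.4,
 "g_ks": 1.0,
 "g_kr": 0.3,
 "g_k1": 7.0,
 "g_sk": 0.5,
 "i_nak_max": 70.8253,
 "k_naca": 0.0374842,
 "i_cap_max": 4.0,
 "g_nab": 0.060599,
 "g_cab": 0.078681,
 "k_o": 5.3,
 "na_o": 130.0,
 "ca_o": 1.8,
 "cm": 66.0,
 "i_up_max": 2352.0,
 "phi_na_en": -1.68
}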