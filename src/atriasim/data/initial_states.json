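{
 "_meta": {
  "description": "Settled resting states: myocyte relaxed 30 s quiescent then pinned to the canonical start (Vm -79.83 mV, Na_i 8.5547 mM, K_i 129.43 mM); fibroblast relaxed 20 s at its -47.75 mV rest.",
  "version": "1.0"
 },
 "myocyte": {
  "V": -79.83,
  "m": 0.0016554285508913762,
  "h1": 0.9540913877963241,
  "h2": 0.9540924991750973,
  "d": 5.0996586354883895e-06,
  "f1": 0.9993664166894926,
  "f2": 0.9993664235500953,
  "r_t": 0.000652130555161652,
  "s_t": 0.9679233825548994,
  "r_sus": 8.086944240909546e-05,
  "s_sus": 0.99897899754337,
  "n_ks": 0.0003930879523138275,
  "pa": 2.0808501992736307e-05,
  "F1": 0.7638924014362037,
  "F2": 0.005475895987726982,
  "O_C": 0.028078697480213535,
  "O_TC": 0.013565043048669989,
  "O_TMgC": 0.19672104918477878,
  "O_TMgMg": 0.7088589504436698,
  "O_Calse": 0.42834628560788496,
  "Na_i": 8.5547,
  "K_i": 129.43,
  "Ca_i": 6.875799270926174e-05,
  "Ca_d": 6.875856882994584e-05,
  "Ca_up": 0.6244754631758596,
  "Ca_rel": 0.6244254536586381
 },
 "fibroblast": {
  "V": -47.75,
  "r_kv": 0.07428280946970214,
  "s_kv": 0.9716854027995463
 }
}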