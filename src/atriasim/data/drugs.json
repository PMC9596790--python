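{
  "_meta": {
    "description": "Single-pore-channel block constants: clinical free plasma concentration and per-channel IC50, both in uM.",
    "version": "1.0"
  },
  "amiodarone": {"concentration": 0.8,
                 "ic50": {"IKr": 0.9, "ICaL": 1.3, "INa": 4.6}},
  "dofetilide": {"concentration": 0.005,
                 "ic50": {"IKr": 0.002, "ICaL": 0.006, "INa": 0.006}},
  "sotalol":    {"concentration": 86.3,
                 "ic50": {"IKr": 2100.0, "ICaL": 2100.0, "INa": 2.1}}
}
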