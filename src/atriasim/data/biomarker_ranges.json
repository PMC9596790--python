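{
  "_meta": {
    "description": "Population-calibration acceptance ranges for plane-averaged biomarkers on the 0%-fibrosis calibration strip: APD90 ms, CV cm/s, RMP mV, Peak = AP amplitude mV (this model family runs a larger upstroke amplitude than microelectrode references; the Peak band is centred on the baseline model).",
    "version": "1.0"
  },
  "APD90": [100.0, 350.0],
  "CV": [35.0, 100.0],
  "RMP": [-90.0, -65.0],
  "Peak": [90.0, 220.0]
}
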