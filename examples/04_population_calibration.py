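"""Generate electrophysiological profiles by Latin Hypercube sampling and
calibrate them against physiological biomarker ranges on a small strip.

Each profile scales nine model parameters by -50%..+100%; a profile is kept
only if its simulated APD90, CV, RMP and amplitude all fall inside the
shipped acceptance ranges (a down-scaled version of the population pipeline;
the full study uses 500 candidates on an 8x256 strip).
"""

from atriasim import (StimulusProtocol, TissueGeometry, calibrate_population,
                      lhs_sample)

candidates = lhs_sample(8, seed=42)
result = calibrate_population(
    candidates,
    geometry=TissueGeometry(nx=48, ny=4, fibrosis_fraction=0.0),
    protocol=StimulusProtocol.scaled(48, n_pulses=3))

cols = ["profile_id", "gNa", "gK1", "D", "APD90", "CV", "RMP",
        "accepted", "reason"]
print(result.provenance[cols].round(2).to_string(index=False))
print(f"\naccepted {len(result.accepted)} of {len(candidates)} candidates; "
      "rejections list the violated range or the conduction failure.")
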