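"""Apply the pore-block antiarrhythmic drugs to the baseline plane and
report the drug-induced change in conduction velocity.

Each drug divides its target conductances by (1 + [C_d]/IC50): amiodarone
and dofetilide slow conduction; sotalol's Table constants make it a
near-total Na-channel block, which abolishes propagation.
"""

from atriasim import (biomarker_delta, biomarkers_from_result, get_drug,
                      load_drug_table, run_simulation, toy_plane)

for name, spec in load_drug_table().items():
    fs = ", ".join(f"{ch} x{f:.3f}" for ch, f in spec.factors().items())
    print(f"{name:<11} ({spec.concentration} uM): {fs}")

bundle = toy_plane(20, 20, fraction=0.0, n_pulses=2)
basal = biomarkers_from_result(
    run_simulation(bundle.geometry, protocol=bundle.protocol))
print(f"\nbasal: CV = {basal.cv:.1f} cm/s")
for name in ("amiodarone", "dofetilide", "sotalol"):
    res = run_simulation(bundle.geometry, drug=get_drug(name),
                         protocol=bundle.protocol)
    bm = biomarkers_from_result(res, drug=name)
    if bm.conducted:
        d = biomarker_delta(bm, basal)
        print(f"{name:<11}: CV = {bm.cv:.1f} cm/s  (dCV = {d.d_cv:+.2f})")
    else:
        print(f"{name:<11}: conduction block")
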