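"""Train the four conduction-block classifiers on a surrogate feature table
with a known decision rule and rank the features.

The surrogate mimics the study schema (nine profile modifiers, three drug
conductance factors, fibrosis level); labels follow a sodium-availability
rule with 10% label noise, so the Bayes-optimal accuracy is 90%.
"""

from atriasim import rank_features, surrogate_ml_dataset, train_models

df = surrogate_ml_dataset(1500, rule="sodium_product", noise_rate=0.1,
                          margin=0.05, seed=7)
reports = train_models(df, split_seed=7)
for r in reports:
    s = r.metrics["sensitivity"]["value"]
    sp = r.metrics["specificity"]["value"]
    print(f"{r.name:<5} accuracy {r.accuracy:5.1f}%  AUC {r.auc:.3f}  "
          f"sens {s:5.1f}%  spec {sp:5.1f}%  (test n={r.split['n_test']})")

csvm = next(r for r in reports if r.name == "CSVM")
rk = rank_features(csvm, df, seed=7)
print("\ntop features (SVM magnitude):",
      ", ".join(rk["sv_magnitude"]["ranking"][:4]))
print("top features (permutation):  ",
      ", ".join(rk["permutation"]["ranking"][:4]))
print("\nThe sodium-related inputs (factor_INa, gNa) should lead both"
      "\nrankings, mirroring the known labeling rule.")
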