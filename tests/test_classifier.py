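"""Conduction-block classifiers: features, metrics, training, ranking."""

import math

import numpy as np
import pandas as pd
import pytest

from atriasim import (assemble_features, evaluate, lhs_sample, rank_features,
                      surrogate_ml_dataset, train_models, wilson_interval)
from atriasim.classifier import FEATURE_COLUMNS, LABEL_COLUMN
from atriasim.pharmacology import load_drug_table


def _biomarker_table(profile_ids, fibroses=(0.0, 5.0, 10.0),
                     drugs=("none", "amiodarone", "dofetilide", "sotalol")):
    rows = []
    for pid in profile_ids:
        for fib in fibroses:
            for d in drugs:
                rows.append({"profile_id": pid, "fibrosis_pct": fib,
                             "drug": d, "conducted": (d != "sotalol")})
    return pd.DataFrame(rows)


class TestAssembleFeatures:
    def test_row_count_is_run_matrix_size(self):
        profiles = lhs_sample(2, seed=0)
        df = assemble_features(_biomarker_table([0, 1]), profiles,
                               load_drug_table())
        assert len(df) == 2 * 3 * 4
        assert list(df.columns) == list(FEATURE_COLUMNS) + [LABEL_COLUMN]

    def test_no_drug_rows_have_unit_factors(self):
        profiles = lhs_sample(1, seed=0)
        df = assemble_features(_biomarker_table([0]), profiles,
                               load_drug_table())
        none_rows = df[df["factor_IKr"] == 1.0]
        sub = _biomarker_table([0])
        assert (sub["drug"] == "none").sum() <= len(none_rows)

    def test_dofetilide_rows_carry_ikr_factor(self):
        profiles = lhs_sample(1, seed=0)
        table = _biomarker_table([0], drugs=("dofetilide",))
        df = assemble_features(table, profiles, load_drug_table())
        assert np.allclose(df["factor_IKr"], 1.0 / 3.5)

    def test_missing_label_names_the_run(self):
        profiles = lhs_sample(1, seed=0)
        table = _biomarker_table([0]).drop(columns=["conducted"])
        with pytest.raises(ValueError, match="profile=0"):
            assemble_features(table, profiles, load_drug_table())

    def test_missing_profile_rejected(self):
        with pytest.raises(ValueError, match="no profile"):
            assemble_features(_biomarker_table([3]), lhs_sample(1, seed=0),
                              load_drug_table())


class TestEvaluate:
    def test_hand_confusion_matrix(self):
        m = evaluate(tp=9, fn=1, tn=8, fp=2)
        assert m["sensitivity"]["value"] == pytest.approx(90.0)
        assert m["specificity"]["value"] == pytest.approx(80.0)
        assert m["ppv"]["value"] == pytest.approx(81.818, abs=1e-2)
        assert m["npv"]["value"] == pytest.approx(88.889, abs=1e-2)
        assert m["accuracy"]["value"] == pytest.approx(85.0)
        assert sum(m["confusion"].values()) == 20

    def test_zero_denominator_reported_as_na(self):
        m = evaluate(tp=0, fn=0, tn=5, fp=5)
        assert m["sensitivity"] is None
        assert m["specificity"]["value"] == 50.0

    def test_perfect_scores_auc_one(self):
        y = np.array([0, 0, 1, 1])
        s = np.array([-2.0, -1.0, 1.0, 2.0])
        m = evaluate(2, 0, 2, 0, y_true=y, scores=s)
        assert m["auc"] == 1.0

    def test_random_scores_auc_half(self):
        rng = np.random.default_rng(42)
        y = rng.integers(0, 2, size=2000)
        s = rng.normal(size=2000)
        m = evaluate(1, 1, 1, 1, y_true=y, scores=s)
        assert abs(m["auc"] - 0.5) < 0.03

    def test_auc_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(1)
        y = rng.integers(0, 2, size=500)
        s = rng.normal(size=500)
        a1 = evaluate(1, 1, 1, 1, y_true=y, scores=s)["auc"]
        a2 = evaluate(1, 1, 1, 1, y_true=y, scores=np.exp(3 * s) + 7)["auc"]
        assert a1 == pytest.approx(a2, abs=1e-12)

    def test_wilson_interval_contains_proportion(self):
        lo, hi = wilson_interval(90, 100)
        assert lo < 0.9 < hi
        assert wilson_interval(0, 0) == (pytest.approx(math.nan, nan_ok=True),
                                         pytest.approx(math.nan, nan_ok=True))

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            evaluate(-1, 0, 0, 1)


class TestTrainModels:
    def test_split_sizes_floor_rule(self):
        df = surrogate_ml_dataset(1032, rule="single_feature", margin=0.1,
                                  seed=0)
        r = train_models(df, split_seed=0, models=["DT"])[0]
        assert r.split["n_train"] == 826
        assert r.split["n_test"] == 206

    def test_stratified_split_preserves_class_ratio(self):
        df = surrogate_ml_dataset(1000, rule="sodium_product", seed=1)
        r = train_models(df, split_seed=0, models=["DT"])[0]
        cm = r.metrics["confusion"]
        test_pos = cm["tp"] + cm["fn"]
        overall = df[LABEL_COLUMN].mean()
        assert abs(test_pos / r.split["n_test"] - overall) < 0.01

    def test_separable_data_all_models_perfect(self):
        df = surrogate_ml_dataset(500, rule="sodium_product", margin=0.45,
                                  seed=2)
        reports = train_models(df, split_seed=0)
        assert {r.name for r in reports} == {"QSVM", "CSVM", "DT", "KNN"}
        for r in reports:
            assert r.accuracy == 100.0

    def test_deterministic_under_seed(self):
        df = surrogate_ml_dataset(400, rule="sodium_product", noise_rate=0.05,
                                  seed=3)
        a = train_models(df, split_seed=7, models=["QSVM"])[0]
        b = train_models(df, split_seed=7, models=["QSVM"])[0]
        assert a.metrics["confusion"] == b.metrics["confusion"]
        assert a.metrics["accuracy"] == b.metrics["accuracy"]
        assert a.best_params == b.best_params

    def test_single_class_rejected(self):
        df = surrogate_ml_dataset(50, rule="single_feature", seed=0)
        df[LABEL_COLUMN] = 1
        with pytest.raises(ValueError):
            train_models(df, split_seed=0)

    def test_metrics_recomputable_from_confusion(self):
        df = surrogate_ml_dataset(600, rule="sodium_product", noise_rate=0.1,
                                  seed=4)
        r = train_models(df, split_seed=0, models=["CSVM"])[0]
        cm = r.metrics["confusion"]
        again = evaluate(cm["tp"], cm["fn"], cm["tn"], cm["fp"])
        assert again["accuracy"]["value"] == r.metrics["accuracy"]["value"]
        assert cm["tp"] + cm["fn"] + cm["tn"] + cm["fp"] == r.split["n_test"]


class TestRankFeatures:
    def test_planted_signal_ranked_first_by_both_methods(self):
        df = surrogate_ml_dataset(600, rule="single_feature", margin=0.2,
                                  seed=5)
        rep = train_models(df, split_seed=0, models=["CSVM"])[0]
        rk = rank_features(rep, df, seed=0)
        assert rk["sv_magnitude"]["ranking"][0] == "gNa"
        assert rk["permutation"]["ranking"][0] == "gNa"
        assert rk["agreement"]

    def test_shuffled_labels_near_uniform_importance(self):
        rng = np.random.default_rng(0)
        df = surrogate_ml_dataset(600, rule="single_feature", margin=0.2,
                                  seed=5)
        df[LABEL_COLUMN] = rng.permutation(df[LABEL_COLUMN].to_numpy())
        rep = train_models(df, split_seed=0, models=["CSVM"])[0]
        rk = rank_features(rep, df, seed=0)
        imp = np.array(list(rk["permutation"]["scores"].values()))
        sds = np.array(list(rk["permutation"]["sd"].values()))
        # no feature stands out from the null: each mean importance sits
        # within 3x its spread across repeats, and all are near zero
        assert np.all(imp < 3.0 * sds + 1e-9)
        assert imp.max() < 0.1
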