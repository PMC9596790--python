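"""Conduction-block classifiers over the simulated run matrix.

Features are the nine profile percent-modifiers, the three drug-induced
conductance factors G_i/G_0 (1.0 without drug) and the fibrosis percentage;
the label is 1 = the plane conducted, 0 = block.  Four model families are
trained: polynomial-kernel SVMs of degree 2 (QSVM) and 3 (CSVM), a decision
tree and K-nearest neighbours.  Hyperparameters are selected by 10-fold
cross-validation inside a stratified 80:20 train/test split; reported
metrics come from the held-out 20% with Wilson-score confidence intervals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.inspection import permutation_importance
from sklearn.metrics import confusion_matrix, roc_auc_score, roc_curve
from sklearn.model_selection import GridSearchCV, StratifiedKFold, \
    train_test_split
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .cell_models import PROFILE_PARAMETERS
from .pharmacology import DRUG_CHANNELS

__all__ = ["FEATURE_COLUMNS", "assemble_features", "train_models",
           "evaluate", "rank_features", "ClassifierReport", "wilson_interval"]

DRUG_FACTOR_COLUMNS = tuple(f"factor_{ch}" for ch in DRUG_CHANNELS)
FEATURE_COLUMNS = tuple(PROFILE_PARAMETERS) + DRUG_FACTOR_COLUMNS \
    + ("fibrosis_pct",)
LABEL_COLUMN = "conducted"


def assemble_features(biomarker_table: pd.DataFrame,
                      profiles: Sequence,
                      drugs: dict) -> pd.DataFrame:
    """One feature row per simulated (profile, fibrosis, drug) run.

    ``biomarker_table`` needs columns profile_id, fibrosis_pct, drug and
    conducted; ``profiles`` supplies the nine percent-modifiers per
    profile_id and ``drugs`` maps drug name -> DrugSpec (the "none" condition
    is implicit).  A missing conduction label raises with the run identity.
    """
    pmap = {p.profile_id: p for p in profiles}
    rows = []
    for _, r in biomarker_table.iterrows():
        pid = int(r["profile_id"])
        run_id = f"(profile={pid}, fibrosis={r['fibrosis_pct']}, " \
                 f"drug={r['drug']})"
        if pid not in pmap:
            raise ValueError(f"no profile scaling for run {run_id}")
        lab = r.get(LABEL_COLUMN)
        if lab is None or (isinstance(lab, float) and math.isnan(lab)):
            raise ValueError(f"missing conduction label for run {run_id}")
        row = dict(pmap[pid].as_dict())
        factors = {ch: 1.0 for ch in DRUG_CHANNELS}
        if r["drug"] not in (None, "none"):
            spec = drugs.get(r["drug"])
            if spec is None:
                raise ValueError(f"unknown drug in run {run_id}")
            factors.update(spec.factors())
        for ch in DRUG_CHANNELS:
            row[f"factor_{ch}"] = factors[ch]
        row["fibrosis_pct"] = float(r["fibrosis_pct"])
        row[LABEL_COLUMN] = int(bool(lab))
        rows.append(row)
    return pd.DataFrame(rows, columns=list(FEATURE_COLUMNS) + [LABEL_COLUMN])


def wilson_interval(k: int, n: int, z: float = 1.959963984540054) -> tuple:
    """Wilson score interval for a binomial proportion k/n."""
    if n == 0:
        return (math.nan, math.nan)
    p = k / n
    denom = 1.0 + z * z / n
    centre = (p + z * z / (2 * n)) / denom
    half = z * math.sqrt(p * (1 - p) / n + z * z / (4 * n * n)) / denom
    return (max(0.0, centre - half), min(1.0, centre + half))


def evaluate(tp: int, fn: int, tn: int, fp: int,
             y_true: Optional[np.ndarray] = None,
             scores: Optional[np.ndarray] = None) -> dict:
    """The five ratio metrics (percent, with Wilson 95% CIs) from a confusion
    matrix, plus ROC AUC when decision scores are supplied.

    Ratios with a zero denominator are reported as None (not 0).
    """
    if min(tp, fn, tn, fp) < 0 or tp + fn + tn + fp == 0:
        raise ValueError("invalid confusion-matrix counts")

    def ratio(k, n):
        if n == 0:
            return None
        lo, hi = wilson_interval(k, n)
        return {"value": 100.0 * k / n, "ci": (100.0 * lo, 100.0 * hi)}

    out = {
        "sensitivity": ratio(tp, tp + fn),
        "specificity": ratio(tn, tn + fp),
        "ppv": ratio(tp, tp + fp),
        "npv": ratio(tn, tn + fn),
        "accuracy": ratio(tp + tn, tp + fn + tn + fp),
        "confusion": {"tp": tp, "fn": fn, "tn": tn, "fp": fp},
    }
    if scores is not None and y_true is not None \
            and len(np.unique(y_true)) == 2:
        out["auc"] = float(roc_auc_score(y_true, scores))
        fpr, tpr, thr = roc_curve(y_true, scores)
        out["roc"] = {"fpr": fpr.tolist(), "tpr": tpr.tolist()}
    return out


@dataclass
class ClassifierReport:
    name: str
    metrics: dict
    best_params: dict
    cv_accuracy: float
    split: dict
    estimator: object = field(repr=False, default=None)

    @property
    def accuracy(self) -> float:
        return self.metrics["accuracy"]["value"]

    @property
    def auc(self) -> float:
        return self.metrics.get("auc", math.nan)


def _model_grid():
    return {
        "QSVM": (SVC(kernel="poly", degree=2, coef0=1.0),
                 {"model__C": [0.1, 1.0, 10.0]}),
        "CSVM": (SVC(kernel="poly", degree=3, coef0=1.0),
                 {"model__C": [0.1, 1.0, 10.0]}),
        "DT": (DecisionTreeClassifier(random_state=0),
               {"model__max_depth": [3, 5, 8, None]}),
        "KNN": (KNeighborsClassifier(),
                {"model__n_neighbors": [3, 5, 9]}),
    }


def train_models(dataset: pd.DataFrame, split_seed: int = 0,
                 test_size: float = 0.2, cv_folds: int = 10,
                 models: Optional[Sequence[str]] = None) -> list:
    """Train and evaluate the four classifier families.

    Stratified 80:20 split (remainder to the training side); 10-fold CV on
    the training portion selects hyperparameters; the held-out 20% produces
    the reported metrics.  Fully deterministic under ``split_seed``.
    """
    y = dataset[LABEL_COLUMN].to_numpy()
    if len(np.unique(y)) < 2:
        raise ValueError("dataset must contain both classes")
    X = dataset[list(FEATURE_COLUMNS)].to_numpy(dtype=float)
    # floor the test-set size: the remainder goes to the training side
    n_test = max(1, int(len(y) * test_size))
    Xtr, Xte, ytr, yte = train_test_split(
        X, y, test_size=n_test, random_state=split_seed, stratify=y)

    folds = min(cv_folds, int(np.bincount(ytr).min()))
    cv = StratifiedKFold(n_splits=max(2, folds), shuffle=True,
                         random_state=split_seed)
    reports = []
    for name, (est, grid) in _model_grid().items():
        if models is not None and name not in models:
            continue
        pipe = Pipeline([("scale", StandardScaler()), ("model", est)])
        search = GridSearchCV(pipe, grid, cv=cv, scoring="accuracy",
                              n_jobs=1)
        search.fit(Xtr, ytr)
        best = search.best_estimator_
        pred = best.predict(Xte)
        if hasattr(best, "decision_function"):
            scores = best.decision_function(Xte)
        else:
            scores = best.predict_proba(Xte)[:, 1]
        cm = confusion_matrix(yte, pred, labels=[0, 1])
        tn, fp, fn, tp = cm.ravel()
        metrics = evaluate(int(tp), int(fn), int(tn), int(fp),
                           y_true=yte, scores=scores)
        reports.append(ClassifierReport(
            name=name, metrics=metrics,
            best_params=search.best_params_,
            cv_accuracy=float(search.best_score_),
            split={"seed": split_seed, "n_train": len(ytr),
                   "n_test": len(yte), "stratified": True},
            estimator=best))
    return reports


def rank_features(report: ClassifierReport, dataset: pd.DataFrame,
                  seed: int = 0, n_repeats: int = 10) -> dict:
    """Two feature rankings from a trained kernel SVM.

    (a) support-vector magnitude: the per-feature magnitude of the signed
    aggregate of dual coefficient x standardized support-vector feature
    value (the linear part of the polynomial expansion, so uninformative
    features cancel); (b) seeded permutation importance on the full feature
    table.  Both are returned ordered; disagreement in the top feature is
    flagged.
    """
    est = report.estimator
    svm = est.named_steps["model"]
    if not hasattr(svm, "support_vectors_"):
        raise ValueError("feature ranking needs a trained SVM report")
    sv = svm.support_vectors_                      # already standardized
    w = svm.dual_coef_.ravel()                     # alpha_i * y_i
    sv_score = np.abs((w[:, None] * sv).sum(axis=0))
    sv_rank = [FEATURE_COLUMNS[i] for i in np.argsort(sv_score)[::-1]]

    # permutation importance on the held-out test split of the same seed
    X = dataset[list(FEATURE_COLUMNS)].to_numpy(dtype=float)
    y = dataset[LABEL_COLUMN].to_numpy()
    _, Xte, _, yte = train_test_split(
        X, y, test_size=report.split["n_test"],
        random_state=report.split["seed"], stratify=y)
    pi = permutation_importance(est, Xte, yte, n_repeats=n_repeats,
                                random_state=seed, scoring="accuracy")
    pi_rank = [FEATURE_COLUMNS[i] for i in np.argsort(pi.importances_mean)[::-1]]

    return {
        "sv_magnitude": {"ranking": sv_rank,
                         "scores": dict(zip(FEATURE_COLUMNS, sv_score))},
        "permutation": {"ranking": pi_rank,
                        "scores": dict(zip(FEATURE_COLUMNS,
                                           pi.importances_mean)),
                        "sd": dict(zip(FEATURE_COLUMNS, pi.importances_std))},
        "agreement": sv_rank[0] == pi_rank[0],
    }
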