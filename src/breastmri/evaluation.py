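"""Cross-validated diagnostic evaluation of features and feature sets.

Performance of single features (trained univariate thresholds), feature
groups, and the combined selected subset is estimated by stratified 10-fold
cross validation; tunable classifiers select their hyperparameters by
5-fold CV inside each training fold (nested CV), and standardization is
fitted on training folds only — no information from a test fold ever
touches training.  Metrics: sensitivity (malignant = positive),
specificity, overall accuracy and AUC (Mann–Whitney formulation, ties ½).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

logger = logging.getLogger(__name__)

__all__ = [
    "ModelSpec",
    "DEFAULT_MODELS",
    "make_folds",
    "confusion_metrics",
    "roc_auc",
    "youden_threshold",
    "univariate_threshold_eval",
    "cross_validate_subset",
    "evaluate_feature_sets",
    "build_report",
]

POSITIVE = "malignant"


@dataclass
class ModelSpec:
    kind: str  # svm_rbf | naive_bayes_gaussian | knn | logistic_regression
    grid: dict = field(default_factory=dict)
    knn_k: int = 6
    standardize: bool = True

    def display_name(self) -> str:
        return {
            "svm_rbf": "SVM",
            "naive_bayes_gaussian": "NB",
            "knn": f"KNN(n = {self.knn_k})",
            "logistic_regression": "Logistic Regression",
        }[self.kind]


def default_models() -> list[ModelSpec]:
    return [
        ModelSpec("svm_rbf", grid={"clf__C": [0.1, 1.0, 10.0, 100.0],
                                   "clf__gamma": [0.01, 0.1, 1.0]}),
        ModelSpec("naive_bayes_gaussian"),
        ModelSpec("knn", knn_k=6),
        ModelSpec("logistic_regression"),
    ]


DEFAULT_MODELS = default_models()


def _build_estimator(spec: ModelSpec, n_features: int):
    if spec.kind == "svm_rbf":
        clf = SVC(kernel="rbf")
    elif spec.kind == "naive_bayes_gaussian":
        clf = GaussianNB()
    elif spec.kind == "knn":
        clf = KNeighborsClassifier(n_neighbors=spec.knn_k)
    elif spec.kind == "logistic_regression":
        clf = LogisticRegression(max_iter=2000)
    else:
        raise ValueError(f"unknown model kind: {spec.kind}")
    steps = [("scale", StandardScaler())] if spec.standardize else []
    steps.append(("clf", clf))
    pipe = Pipeline(steps)
    grid = dict(spec.grid)
    if spec.kind == "svm_rbf" and "clf__gamma" in grid:
        # gamma grid scaled by 1/n_features
        grid["clf__gamma"] = [g / n_features for g in grid["clf__gamma"]]
    return pipe, grid


def _scores(estimator, X) -> np.ndarray:
    """Continuous decision scores oriented toward the positive class."""
    if hasattr(estimator, "decision_function"):
        return np.asarray(estimator.decision_function(X))
    proba = estimator.predict_proba(X)
    classes = list(estimator.classes_)
    return np.asarray(proba[:, classes.index(POSITIVE)])


# ---------------------------------------------------------------------------
# folds and metrics
# ---------------------------------------------------------------------------


def make_folds(labels, k: int = 10, seed: int = 0) -> np.ndarray:
    """Stratified partition into k folds; returns a fold index per sample.

    Fold sizes differ by at most one, overall and per class.
    """
    y = np.asarray(labels)
    _, counts = np.unique(y, return_counts=True)
    if counts.min() < k:
        raise ValueError(f"smallest class has {counts.min()} samples < k={k}")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    folds = np.empty(len(y), dtype=int)
    for fold_id, (_, test_idx) in enumerate(skf.split(np.zeros(len(y)), y)):
        folds[test_idx] = fold_id
    return folds


def confusion_metrics(predictions, truth, positive: str = POSITIVE) -> dict[str, float]:
    """Sensitivity TP/(TP+FN), specificity TN/(TN+FP), accuracy (TP+TN)/n."""
    pred = np.asarray(predictions)
    y = np.asarray(truth)
    if pred.shape != y.shape:
        raise ValueError("predictions and truth must have equal length")
    pos = y == positive
    neg = ~pos
    tp = int((pred[pos] == positive).sum())
    fn = int(pos.sum()) - tp
    tn = int((pred[neg] != positive).sum())
    fp = int(neg.sum()) - tn
    out = {"accuracy": (tp + tn) / len(y)}
    out["sensitivity"] = tp / (tp + fn) if (tp + fn) > 0 else float("nan")
    out["specificity"] = tn / (tn + fp) if (tn + fp) > 0 else float("nan")
    if not pos.any() or not neg.any():
        logger.warning("confusion_metrics: a class is absent from truth; "
                       "the affected metric is undefined")
    return out


def roc_auc(scores, truth, positive: str = POSITIVE) -> float:
    """AUC = P(random positive outscores random negative), ties counted ½."""
    y = np.asarray(truth)
    s = np.asarray(scores, dtype=float)
    if not np.isfinite(s).all():
        raise ValueError("scores must be finite")
    pos = y == positive
    if not pos.any() or pos.all():
        raise ValueError("both classes must be present for AUC")
    return float(roc_auc_score(pos.astype(int), s))


# ---------------------------------------------------------------------------
# univariate threshold model
# ---------------------------------------------------------------------------


def youden_threshold(values: np.ndarray, labels: np.ndarray,
                     positive: str = POSITIVE) -> tuple[float, int]:
    """Cutoff maximizing the Youden index J = sensitivity + specificity − 1.

    The calling direction (``+1``: values >= threshold call malignant;
    ``-1``: values <= threshold call malignant) is fixed first from the AUC
    orientation of the raw values, then the J-optimal cutoff is taken over
    midpoints of consecutive sorted unique values.
    """
    v = np.asarray(values, dtype=float)
    y = np.asarray(labels)
    auc_raw = roc_auc(v, y, positive)
    direction = 1 if auc_raw >= 0.5 else -1
    scores = direction * v
    uniq = np.unique(scores)
    if uniq.size == 1:
        return float(direction * uniq[0]), direction
    cuts = (uniq[:-1] + uniq[1:]) / 2.0
    pos = y == positive
    best_j, best_cut = -np.inf, cuts[0]
    for cut in cuts:
        called = scores >= cut
        sens = (called & pos).sum() / pos.sum()
        spec = (~called & ~pos).sum() / (~pos).sum()
        j = sens + spec - 1.0
        if j > best_j:
            best_j, best_cut = j, cut
    return float(direction * best_cut), direction


def univariate_threshold_eval(values, labels, folds: np.ndarray,
                              positive: str = POSITIVE) -> dict:
    """Cross-validated single-feature evaluation with trained thresholds.

    Per fold the Youden-optimal cutoff (and its direction) is chosen on the
    training portion and applied to the held-out fold.  Also reports the
    whole-data optimal threshold for reference.
    """
    v = np.asarray(values, dtype=float)
    y = np.asarray(labels)
    if np.unique(v).size == 1:
        logger.warning("constant feature: univariate evaluation is chance-level")
        prevalence = max((y == positive).mean(), (y != positive).mean())
        return {"per_fold": [], "averaged": {"sensitivity": float("nan"),
                                             "specificity": float("nan"),
                                             "accuracy": prevalence,
                                             "auc": 0.5},
                "whole_data_threshold": float(v[0]), "direction": 1,
                "constant_feature": True}
    per_fold = []
    neg_label = np.unique(y[y != positive])[0]
    for fold_id in np.unique(folds):
        train, test = folds != fold_id, folds == fold_id
        thr, direction = youden_threshold(v[train], y[train], positive)
        called = direction * v[test] >= direction * thr
        pred = np.where(called, positive, neg_label)
        m = confusion_metrics(pred, y[test], positive)
        m["auc"] = roc_auc(direction * v[test], y[test], positive)
        m["threshold"] = thr
        m["direction"] = direction
        m["fold"] = int(fold_id)
        per_fold.append(m)
    thr_all, dir_all = youden_threshold(v, y, positive)
    return {"per_fold": per_fold, "averaged": _average(per_fold),
            "whole_data_threshold": thr_all, "direction": dir_all}


def _average(per_fold: list[dict]) -> dict[str, float]:
    keys = ("sensitivity", "specificity", "accuracy", "auc")
    return {k: float(np.mean([f[k] for f in per_fold])) for k in keys}


# ---------------------------------------------------------------------------
# nested cross validation of multi-feature models
# ---------------------------------------------------------------------------


def cross_validate_subset(table: pd.DataFrame, feature_subset: list[str],
                          labels, model: ModelSpec, folds: np.ndarray | None = None,
                          k: int = 10, inner_k: int = 5, seed: int = 0) -> dict:
    """Nested CV of one model on one feature subset.

    Outer stratified k-fold; within each training fold, grid hyperparameters
    (if any) are selected by inner ``inner_k``-fold CV; standardization is
    part of the pipeline so it refits on training data only.  AUC comes from
    continuous decision scores, never hard labels.
    """
    if not feature_subset:
        raise ValueError("feature subset must be non-empty")
    X = table[list(feature_subset)].to_numpy(dtype=float)
    y = np.asarray(labels)
    if folds is None:
        folds = make_folds(y, k=k, seed=seed)
    per_fold = []
    for fold_id in np.unique(folds):
        train, test = folds != fold_id, folds == fold_id
        if min(np.bincount(pd.factorize(y[train])[0])) < inner_k:
            raise ValueError("inner CV infeasible: a training class has "
                             f"fewer than {inner_k} samples")
        pipe, grid = _build_estimator(model, X.shape[1])
        if grid:
            inner = StratifiedKFold(n_splits=inner_k, shuffle=True, random_state=seed)
            est = GridSearchCV(pipe, grid, cv=inner, scoring="accuracy")
        else:
            est = pipe
        est.fit(X[train], y[train])
        pred = est.predict(X[test])
        m = confusion_metrics(pred, y[test])
        m["auc"] = roc_auc(_scores(est, X[test]), y[test])
        m["fold"] = int(fold_id)
        per_fold.append(m)
    return {"model": model.display_name(), "features": list(feature_subset),
            "per_fold": per_fold, "averaged": _average(per_fold)}


# ---------------------------------------------------------------------------
# report assembly
# ---------------------------------------------------------------------------


def evaluate_feature_sets(table: pd.DataFrame, labels,
                          feature_sets: dict[str, list[str]],
                          models: list[ModelSpec] | None = None,
                          k: int = 10, inner_k: int = 5, seed: int = 0) -> dict:
    """Evaluate every feature set: univariate threshold for singletons,
    all classifiers (plus their average) for multi-feature sets."""
    models = models or default_models()
    y = np.asarray(labels)
    folds = make_folds(y, k=k, seed=seed)
    sections = {}
    for set_name, feats in feature_sets.items():
        if len(feats) == 1:
            res = univariate_threshold_eval(table[feats[0]].to_numpy(float), y, folds)
            sections[set_name] = {
                "features": feats,
                "rows": [{"model": "Univariate Threshold",
                          "averaged": res["averaged"],
                          "per_fold": res["per_fold"]}],
                "whole_data_threshold": res.get("whole_data_threshold"),
                "direction": res.get("direction"),
            }
        else:
            rows = [cross_validate_subset(table, feats, y, spec, folds=folds,
                                          inner_k=inner_k, seed=seed)
                    for spec in models]
            averaged_row = {
                "model": "Averaged",
                "averaged": {key: float(np.mean([r["averaged"][key] for r in rows]))
                             for key in ("sensitivity", "specificity", "accuracy", "auc")},
            }
            sections[set_name] = {"features": feats, "rows": rows + [averaged_row]}
    return {"seed": seed, "k": k, "inner_k": inner_k,
            "fold_assignment": folds.tolist(), "sections": sections}


def build_report(table: pd.DataFrame, labels, selected: list[str],
                 feature_sets: dict[str, list[str]],
                 models: list[ModelSpec] | None = None,
                 k: int = 10, inner_k: int = 5, seed: int = 0) -> dict:
    """Full diagnostic report.

    Two parts: a per-selected-feature univariate section (group means ± sd,
    Welch p, whole-data ROC accuracy and threshold) and a per-feature-set ×
    model section with an "Averaged" row per multi-feature set.
    """
    from scipy import stats as sps

    y = np.asarray(labels)
    folds = make_folds(y, k=k, seed=seed)
    pos = y == POSITIVE
    univariate = {}
    for name in selected:
        v = table[name].to_numpy(float)
        welch = sps.ttest_ind(v[pos], v[~pos], equal_var=False)
        thr, direction = youden_threshold(v, y)
        called = direction * v >= direction * thr
        neg_label = np.unique(y[~pos])[0]
        pred = np.where(called, POSITIVE, neg_label)
        whole = confusion_metrics(pred, y)
        cvres = univariate_threshold_eval(v, y, folds)
        univariate[name] = {
            "mean_benign": float(v[~pos].mean()),
            "sd_benign": float(v[~pos].std(ddof=1)),
            "mean_malignant": float(v[pos].mean()),
            "sd_malignant": float(v[pos].std(ddof=1)),
            "welch_p": float(welch.pvalue),
            "whole_data_accuracy": whole["accuracy"],
            "threshold": thr,
            "direction": direction,
            "cv": cvres["averaged"],
        }
    multisection = evaluate_feature_sets(table, y, feature_sets, models,
                                         k=k, inner_k=inner_k, seed=seed)
    report = {"univariate": univariate, "feature_sets": multisection}
    _check_report(report)
    return report


def plot_roc(table: pd.DataFrame, labels, feature_sets: dict[str, list[str]],
             out_path, seed: int = 0) -> None:
    """Whole-data ROC curves per feature set (single features use the raw
    value; multi-feature sets use a cross-fitted logistic score)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from sklearn.metrics import roc_curve
    from sklearn.model_selection import cross_val_predict

    y = (np.asarray(labels) == POSITIVE).astype(int)
    fig, ax = plt.subplots(figsize=(5, 5))
    for name, feats in feature_sets.items():
        if len(feats) == 1:
            scores = table[feats[0]].to_numpy(float)
            if roc_auc_score(y, scores) < 0.5:
                scores = -scores
        else:
            pipe = Pipeline([("scale", StandardScaler()),
                             ("clf", LogisticRegression(max_iter=2000))])
            scores = cross_val_predict(pipe, table[feats].to_numpy(float), y,
                                       cv=StratifiedKFold(5, shuffle=True,
                                                          random_state=seed),
                                       method="predict_proba")[:, 1]
        fpr, tpr, _ = roc_curve(y, scores)
        ax.plot(fpr, tpr, label=f"{name} (AUC {roc_auc_score(y, scores):.2f})")
    ax.plot([0, 1], [0, 1], "k:", lw=0.8)
    ax.set_xlabel("1 - specificity")
    ax.set_ylabel("sensitivity")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(out_path, dpi=150)
    plt.close(fig)


def _check_report(report: dict) -> None:
    """Metric-bound and Averaged-row consistency assertions."""
    for section in report["feature_sets"]["sections"].values():
        model_rows = [r for r in section["rows"] if r["model"] != "Averaged"]
        for row in section["rows"]:
            for key, val in row["averaged"].items():
                if np.isfinite(val):
                    assert -1e-9 <= val <= 1.0 + 1e-9, f"metric {key} out of [0,1]"
        avg_rows = [r for r in section["rows"] if r["model"] == "Averaged"]
        if avg_rows and model_rows:
            for key in ("sensitivity", "specificity", "accuracy", "auc"):
                expect = float(np.mean([r["averaged"][key] for r in model_rows]))
                assert abs(avg_rows[0]["averaged"][key] - expect) < 1e-12
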