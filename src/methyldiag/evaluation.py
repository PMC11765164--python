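"""Cross-validated evaluation: stratified folds, accuracy/recall/F1, ROC/AUC.

The harness trains the diagnosis model (with or without the dynamic residual)
or one of the conventional baselines — logistic regression, SVM, random
forest, gradient-boosted trees (XGBoost), k-NN — under one seeded fold
assignment, so that compared conditions differ only in the model, never in
the splits.  Recall and F1 are computed on the disease (positive) class;
ROC points are pooled over the test folds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn import metrics as skmetrics
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .io import MethylationMatrix, SampleMetadataTable, ValidationError
from .model import DiagnosisModel, TrainConfig, compatible_heads, train_model

__all__ = [
    "CVMetrics",
    "stratified_kfold",
    "binary_metrics",
    "roc_auc",
    "crossval_evaluate",
    "BASELINE_MODELS",
]

BASELINE_MODELS = ("lr", "svm", "rf", "gbt", "knn")


@dataclass
class CVMetrics:
    """Per-fold classification metrics plus pooled ROC/AUC."""

    accuracy: list[float]
    recall: list[float]
    f1: list[float]
    roc_points: np.ndarray  # (n, 2) columns FPR, TPR
    auc: float
    seed: int
    model_spec: str = ""

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(self.accuracy))

    @property
    def mean_recall(self) -> float:
        return float(np.mean(self.recall))

    @property
    def mean_f1(self) -> float:
        return float(np.mean(self.f1))


def stratified_kfold(
    labels: Sequence[int], k: int, seed: int
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Seeded stratified k-fold split; folds partition the sample indices."""
    y = np.asarray(labels, dtype=int)
    if k < 2:
        raise ValidationError("k must be >= 2")
    _, counts = np.unique(y, return_counts=True)
    if counts.min() < k:
        raise ValidationError(
            f"smallest class has {counts.min()} members, fewer than k={k}"
        )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    return [(tr.copy(), te.copy()) for tr, te in skf.split(np.zeros_like(y), y)]


def binary_metrics(
    truth: Sequence[int], predicted: Sequence[int]
) -> tuple[float, float, float]:
    """Accuracy, recall and F1 with disease (label 1) as the positive class."""
    t = np.asarray(truth, dtype=int)
    p = np.asarray(predicted, dtype=int)
    if t.shape != p.shape:
        raise ValidationError("truth and predicted must have equal length")
    accuracy = float(skmetrics.accuracy_score(t, p))
    recall = float(skmetrics.recall_score(t, p, pos_label=1, zero_division=0))
    f1 = float(skmetrics.f1_score(t, p, pos_label=1, zero_division=0))
    return accuracy, recall, f1


def roc_auc(
    truth: Sequence[int], scores: Sequence[float]
) -> tuple[np.ndarray, float]:
    """ROC points (FPR, TPR) by threshold sweep and the concordance AUC.

    AUC equals the probability that a random disease sample outscores a
    random healthy one, ties counted one half.
    """
    t = np.asarray(truth, dtype=int)
    s = np.asarray(scores, dtype=float)
    if t.shape != s.shape:
        raise ValidationError("truth and scores must have equal length")
    if np.unique(t).size < 2:
        raise ValidationError("ROC needs both classes present")
    fpr, tpr, _ = skmetrics.roc_curve(t, s, drop_intermediate=False)
    auc = float(skmetrics.roc_auc_score(t, s))
    return np.column_stack([fpr, tpr]), auc


def _make_baseline(spec: str, seed: int):
    if spec == "lr":
        return make_pipeline(
            StandardScaler(), LogisticRegression(max_iter=1000)
        )
    if spec == "svm":
        return make_pipeline(StandardScaler(), SVC(random_state=seed))
    if spec == "rf":
        return RandomForestClassifier(random_state=seed, n_jobs=1)
    if spec == "gbt":
        from xgboost import XGBClassifier

        return XGBClassifier(random_state=seed, n_jobs=1, verbosity=0)
    if spec == "knn":
        return make_pipeline(StandardScaler(), KNeighborsClassifier())
    raise ValidationError(f"unknown model spec {spec!r}")


def _baseline_scores(clf, X: np.ndarray) -> np.ndarray:
    if hasattr(clf, "predict_proba"):
        try:
            return clf.predict_proba(X)[:, 1]
        except AttributeError:  # pragma: no cover
            pass
    return clf.decision_function(X)


def crossval_evaluate(
    matrix: MethylationMatrix,
    metadata: SampleMetadataTable,
    tissue: str | None,
    sites: Sequence[str],
    model_spec: str = "transformer",
    k: int = 5,
    seed: int = 0,
    train_config: TrainConfig | None = None,
    model_args: dict | None = None,
) -> CVMetrics:
    """k-fold cross-validated metrics for one model on one tissue's cohort.

    ``model_spec`` is ``"transformer"`` (dynamic residual on), ``"baseline"``
    (residual off) or one of the conventional learners ``"lr"``, ``"svm"``,
    ``"rf"``, ``"gbt"``, ``"knn"``.  ``tissue=None`` uses every sample.
    Missing betas are mean-imputed per training fold.
    """
    sample_ids = metadata.select(tissue=tissue) if tissue else metadata.sample_ids
    if not sample_ids:
        raise ValidationError(f"no samples for tissue {tissue!r}")
    y = metadata.status_for(sample_ids)
    sub = matrix.subset_samples(sample_ids).subset_sites(list(sites))
    X = sub.betas
    folds = stratified_kfold(y, k, seed)
    model_args = dict(model_args or {})

    accs, recs, f1s = [], [], []
    pooled_truth: list[np.ndarray] = []
    pooled_scores: list[np.ndarray] = []
    for fold_i, (tr, te) in enumerate(folds):
        X_tr, X_te = X[tr].copy(), X[te].copy()
        col_mean = np.nanmean(X_tr, axis=0)
        col_mean = np.where(np.isnan(col_mean), 0.5, col_mean)
        for arr in (X_tr, X_te):
            nan_r, nan_c = np.where(np.isnan(arr))
            arr[nan_r, nan_c] = col_mean[nan_c]
        if model_spec in ("transformer", "baseline"):
            cfg = train_config or TrainConfig()
            cfg = TrainConfig(**{**cfg.__dict__, "seed": cfg.seed + fold_i})
            margs = dict(model_args)
            margs.setdefault("use_dynamic_residual", model_spec == "transformer")
            if margs.get("token_layout", "single") == "single":
                margs.setdefault("heads", compatible_heads(X.shape[1]))
            model, _ = train_model(X_tr, y[tr], cfg, **margs)
            scores = model.predict_proba(X_te)[:, 1]
            pred = (scores >= 0.5).astype(int)
        elif model_spec in BASELINE_MODELS:
            clf = _make_baseline(model_spec, seed + fold_i)
            clf.fit(X_tr, y[tr])
            scores = _baseline_scores(clf, X_te)
            pred = clf.predict(X_te)
        else:
            raise ValidationError(f"unknown model spec {model_spec!r}")
        a, r, f = binary_metrics(y[te], pred)
        accs.append(a)
        recs.append(r)
        f1s.append(f)
        pooled_truth.append(y[te])
        pooled_scores.append(scores)

    truth_all = np.concatenate(pooled_truth)
    scores_all = np.concatenate(pooled_scores)
    points, auc = roc_auc(truth_all, scores_all)
    return CVMetrics(
        accuracy=accs,
        recall=recs,
        f1=f1s,
        roc_points=points,
        auc=auc,
        seed=seed,
        model_spec=model_spec,
    )
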