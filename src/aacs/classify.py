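"""Classification stack: discriminants, random-subspace ensemble, CV, ROC.

The detection classifier follows the discriminant-analysis family (groups
assumed multivariate normal): linear/quadratic discriminants as base
learners, combined in a random-subspace ensemble — each of B weak
learners sees m of the d signature channels (default 30 learners, 3 of
5), their class posteriors are averaged, and the argmax wins (lowest
class index on ties).  Cross-validation is replicate-aware: technical
replicates are collapsed to patient means before any split, so no
patient's information leaks between training and validation folds.
Operating points are selected on out-of-fold scores by maximising
sensitivity under a specificity floor (100% specificity in the screening
setting).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.discriminant_analysis import (
    LinearDiscriminantAnalysis,
    QuadraticDiscriminantAnalysis,
)
from sklearn.metrics import auc as _sk_auc
from sklearn.metrics import roc_curve as _sk_roc_curve
from sklearn.model_selection import KFold, StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import LinearSVC


class ClassifyError(ValueError):
    pass


class DiscriminantClassifier:
    """Linear (pooled covariance) or quadratic (per-class) discriminant.

    ``score`` returns class posterior probabilities with equal priors by
    default; ``regularization`` shrinks the covariance estimate (linear:
    shrinkage in [0,1]; quadratic: scipy-style reg_param).
    """

    def __init__(self, kind: str = "linear", regularization: float = 0.0,
                 priors: str = "equal"):
        if kind not in ("linear", "quadratic"):
            raise ClassifyError(f"unknown discriminant kind {kind!r}")
        self.kind = kind
        self.regularization = regularization
        self.priors = priors
        self._model = None

    def _make(self, n_classes: int):
        priors = None if self.priors == "empirical" else np.full(n_classes, 1.0 / n_classes)
        if self.kind == "linear":
            if self.regularization > 0:
                return LinearDiscriminantAnalysis(
                    solver="lsqr", shrinkage=self.regularization, priors=priors
                )
            return LinearDiscriminantAnalysis(priors=priors)
        return QuadraticDiscriminantAnalysis(
            reg_param=self.regularization, priors=priors
        )

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        classes, counts = np.unique(y, return_counts=True)
        if len(classes) < 2:
            raise ClassifyError("need >= 2 classes")
        if (counts < 2).any():
            raise ClassifyError("each class needs >= 2 training samples")
        self._model = self._make(len(classes))
        try:
            self._model.fit(X, y)
        except np.linalg.LinAlgError as exc:
            raise ClassifyError(
                "singular covariance; increase regularization"
            ) from exc
        self.classes_ = self._model.classes_
        return self

    def score(self, X) -> np.ndarray:
        return self._model.predict_proba(np.asarray(X, dtype=float))

    def predict(self, X):
        return self.classes_[np.argmax(self.score(X), axis=1)]


class KNNClassifier:
    """Distance-weighted k-nearest-neighbour base learner.

    Features are standardized on the training data first: signature
    channels span orders of magnitude (mM-scale lysine vs uM-scale free
    cysteine) and unscaled Euclidean distance would see only the largest.
    """

    def __init__(self, n_neighbors: int = 5, weights: str = "distance"):
        self.n_neighbors = n_neighbors
        self.weights = weights

    def fit(self, X, y):
        y = np.asarray(y)
        k = min(self.n_neighbors, len(y))
        self._model = make_pipeline(
            StandardScaler(),
            KNeighborsClassifier(n_neighbors=k, weights=self.weights),
        )
        self._model.fit(np.asarray(X, dtype=float), y)
        self.classes_ = self._model.named_steps["kneighborsclassifier"].classes_
        return self

    def score(self, X) -> np.ndarray:
        return self._model.predict_proba(np.asarray(X, dtype=float))

    def predict(self, X):
        return self.classes_[np.argmax(self.score(X), axis=1)]


class LinearSVMClassifier:
    """L2-regularized hinge-loss linear SVM, standardized on the training fold.

    ``score`` returns a two-column matrix [(-margin, +margin)] so argmax and
    ROC use the signed decision value; ``linear_weights()`` exposes the
    decision function in the *original* feature space for SHAP.
    """

    def __init__(self, C: float = 1.0, max_iter: int = 20000):
        self.C = C
        self.max_iter = max_iter

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if len(np.unique(y)) != 2:
            raise ClassifyError("linear SVM here is binary-only")
        self._pipe = make_pipeline(
            StandardScaler(),
            LinearSVC(C=self.C, loss="hinge", max_iter=self.max_iter),
        )
        self._pipe.fit(X, y)
        self.classes_ = self._pipe.named_steps["linearsvc"].classes_
        return self

    def decision_function(self, X) -> np.ndarray:
        return self._pipe.decision_function(np.asarray(X, dtype=float))

    def score(self, X) -> np.ndarray:
        d = self.decision_function(X)
        return np.column_stack([-d, d])

    def predict(self, X):
        return self.classes_[(self.decision_function(X) > 0).astype(int)]

    def linear_weights(self) -> tuple[np.ndarray, float]:
        scaler = self._pipe.named_steps["standardscaler"]
        svc = self._pipe.named_steps["linearsvc"]
        w_std = svc.coef_.ravel()
        w = w_std / scaler.scale_
        b = float(svc.intercept_[0] - (w_std * scaler.mean_ / scaler.scale_).sum())
        return w, b


def train_discriminant(X, y, kind: str = "linear", regularization: float = 0.0):
    return DiscriminantClassifier(kind, regularization).fit(X, y)


@dataclass(frozen=True)
class SubspaceEnsembleConfig:
    """Random-subspace ensemble settings (B learners over m of d channels)."""

    n_learners: int = 30
    subspace_size: int = 3
    n_dims: int = 5
    base: str = "discriminant"  # "discriminant" | "knn"
    base_kind: str = "linear"
    regularization: float = 0.0
    n_neighbors: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if not 1 <= self.subspace_size <= self.n_dims:
            raise ClassifyError("need 1 <= subspace_size <= n_dims")
        if self.n_learners < 1:
            raise ClassifyError("need at least one learner")


class SubspaceEnsemble:
    """Average-posterior random-subspace ensemble over weak learners.

    Each learner independently draws ``subspace_size`` of the feature
    dimensions uniformly without replacement (seeded, independent across
    learners), fits its base classifier on those columns, and the
    ensemble score is the mean per-learner class-posterior matrix.
    Prediction is argmax with lowest-class-index tie-break.
    """

    def __init__(self, config: SubspaceEnsembleConfig):
        self.config = config

    def _base(self):
        if self.config.base == "knn":
            return KNNClassifier(self.config.n_neighbors)
        return DiscriminantClassifier(
            self.config.base_kind, self.config.regularization
        )

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        cfg = self.config
        if X.shape[1] != cfg.n_dims:
            raise ClassifyError(
                f"expected {cfg.n_dims} feature dims, got {X.shape[1]}"
            )
        rng = np.random.default_rng(cfg.seed)
        self.subspaces_ = [
            np.sort(rng.choice(cfg.n_dims, cfg.subspace_size, replace=False))
            for _ in range(cfg.n_learners)
        ]
        self.learners_ = [
            self._base().fit(X[:, cols], y) for cols in self.subspaces_
        ]
        self.classes_ = self.learners_[0].classes_
        return self

    def score(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        total = np.zeros((X.shape[0], len(self.classes_)))
        for cols, learner in zip(self.subspaces_, self.learners_):
            total += learner.score(X[:, cols])
        return total / len(self.learners_)

    def predict(self, X):
        return self.classes_[np.argmax(self.score(X), axis=1)]


def train_subspace_ensemble(X, y, config: SubspaceEnsembleConfig):
    return SubspaceEnsemble(config).fit(X, y)


@dataclass(frozen=True)
class CVPlan:
    """Replicate-aware (stratified) k-fold plan; k='loo' for leave-one-out."""

    k: int | str = 5
    stratified: bool = True
    collapse_replicates: bool = True
    seed: int = 0


@dataclass
class CVResult:
    scores: pd.DataFrame  # one row per patient: label, fold, per-class scores
    fold_assignments: pd.DataFrame  # sample_id, fold, role (train appears too)
    fold_accuracies: list[float]
    classes: list

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(self.fold_accuracies))

    def positive_scores(self, positive_label) -> tuple[np.ndarray, np.ndarray]:
        col = f"score_{positive_label}"
        return (
            self.scores[col].to_numpy(),
            (self.scores["label"] == positive_label).to_numpy().astype(int),
        )


def collapse_replicates(features: pd.DataFrame, channels: list[str]) -> pd.DataFrame:
    """Mean of technical replicates per sample_id (done before any split)."""
    return (
        features.groupby("sample_id", sort=False)[channels]
        .mean()
        .reset_index()
    )


def crossvalidate(
    features: pd.DataFrame,
    labels: pd.DataFrame,
    channels: list[str],
    classifier_factory,
    plan: CVPlan = CVPlan(),
) -> CVResult:
    """Out-of-fold scoring with patient-level folds.

    ``features`` may contain replicate rows (sample_id repeated); they are
    collapsed to patient means first when the plan says so.  Folds are
    stratified by label with a seeded shuffle; every patient lands in
    exactly one validation fold.
    """
    if plan.collapse_replicates:
        feats = collapse_replicates(features, channels)
    else:
        feats = features[["sample_id", *channels]].copy()
        if feats["sample_id"].duplicated().any():
            raise ClassifyError("duplicate sample_ids without replicate collapse")
    merged = feats.merge(labels[["sample_id", "label"]], on="sample_id",
                         validate="one_to_one")
    X = merged[channels].to_numpy(dtype=float)
    y = merged["label"].to_numpy()
    n = len(merged)
    classes, counts = np.unique(y, return_counts=True)
    if plan.k == "loo":
        splits = [(np.setdiff1d(np.arange(n), [i]), np.array([i]))
                  for i in range(n)]
    else:
        k = int(plan.k)
        if (counts < k).any() and plan.stratified:
            raise ClassifyError(
                f"smallest class ({counts.min()}) has fewer members than k={k}"
            )
        cv = (StratifiedKFold(k, shuffle=True, random_state=plan.seed)
              if plan.stratified
              else KFold(k, shuffle=True, random_state=plan.seed))
        splits = list(cv.split(X, y))

    score_rows = []
    assign_rows = []
    accuracies = []
    for fold, (tr, va) in enumerate(splits):
        if np.intersect1d(tr, va).size:
            raise ClassifyError("train/validation overlap")  # pragma: no cover
        model = classifier_factory()
        model.fit(X[tr], y[tr])
        scores = model.score(X[va])
        preds = model.classes_[np.argmax(scores, axis=1)]
        accuracies.append(float((preds == y[va]).mean()))
        for row_i, idx in enumerate(va):
            row = {"sample_id": merged["sample_id"].iloc[idx],
                   "label": y[idx], "fold": fold,
                   "prediction": preds[row_i]}
            for ci, cls in enumerate(model.classes_):
                row[f"score_{cls}"] = float(scores[row_i, ci])
            score_rows.append(row)
        for idx in tr:
            assign_rows.append({"sample_id": merged["sample_id"].iloc[idx],
                                "fold": fold, "role": "train"})
        for idx in va:
            assign_rows.append({"sample_id": merged["sample_id"].iloc[idx],
                                "fold": fold, "role": "validation"})
    scores_df = pd.DataFrame(score_rows)
    if scores_df["sample_id"].duplicated().any():
        raise ClassifyError("a patient appears in more than one validation fold")
    return CVResult(scores_df, pd.DataFrame(assign_rows), accuracies,
                    list(classes))


@dataclass
class RocResult:
    thresholds: np.ndarray
    sensitivity: np.ndarray
    fpr: np.ndarray
    auroc: float
    operating_point: dict | None = None


def roc_metrics(scores, labels) -> RocResult:
    """ROC curve and AUROC (trapezoid == normalized Mann-Whitney U)."""
    y = np.asarray(labels).astype(int)
    s = np.asarray(scores, dtype=float)
    if len(np.unique(y)) < 2:
        raise ClassifyError("ROC needs both classes present")
    fpr, tpr, thr = _sk_roc_curve(y, s, drop_intermediate=False)
    return RocResult(thr, tpr, fpr, float(_sk_auc(fpr, tpr)))


def select_operating_point(
    scores, labels, specificity_floor: float = 1.0
) -> dict:
    """Maximum-sensitivity threshold with specificity >= floor.

    Candidate cuts admit scores >= s for each unique score s (plus the
    admit-nothing cut); the returned threshold is the midpoint between the
    lowest admitted score and the highest score below it.
    """
    y = np.asarray(labels).astype(int)
    s = np.asarray(scores, dtype=float)
    if not 0.0 <= specificity_floor <= 1.0:
        raise ClassifyError("specificity floor must be in [0, 1]")
    uniq = np.sort(np.unique(s))[::-1]
    n_pos = int(y.sum())
    n_neg = len(y) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ClassifyError("operating point needs both classes")
    feasible = []
    for cut in list(uniq) + [np.inf]:
        pred = s >= cut
        tp = int((pred & (y == 1)).sum())
        fp = int((pred & (y == 0)).sum())
        sens = tp / n_pos
        spec = 1.0 - fp / n_neg
        if spec >= specificity_floor:
            feasible.append((float(cut), sens, spec))
    best = None
    if feasible:
        best_sens = max(f[1] for f in feasible)
        # among max-sensitivity cuts, take the most permissive threshold
        cut, sens, spec = min(f for f in feasible if f[1] == best_sens)
        below = s[s < cut]
        if np.isinf(cut):
            threshold = float(s.max()) + 1.0
        elif below.size:
            threshold = float((cut + below.max()) / 2.0)
        else:
            threshold = float(cut) - 1.0
        best = {"threshold": threshold, "sensitivity": float(sens),
                "specificity": float(spec)}
    if best is None:
        raise ClassifyError(
            f"no operating point reaches specificity >= {specificity_floor}"
        )
    return best


@dataclass
class BinaryMetrics:
    tp: int
    fp: int
    tn: int
    fn: int
    sensitivity: float
    specificity: float
    ppv: float | None
    fdr: float | None
    flags: list[str] = field(default_factory=list)

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def evaluate_binary(predictions, labels, positive=1) -> BinaryMetrics:
    pred = np.asarray(predictions)
    y = np.asarray(labels)
    if pred.shape != y.shape or pred.size == 0:
        raise ClassifyError("predictions and labels must align and be non-empty")
    p = pred == positive
    t = y == positive
    tp = int((p & t).sum())
    fp = int((p & ~t).sum())
    tn = int((~p & ~t).sum())
    fn = int((~p & t).sum())
    sens = tp / (tp + fn) if (tp + fn) else float("nan")
    spec = tn / (tn + fp) if (tn + fp) else float("nan")
    flags = []
    if tp + fp == 0:
        ppv = fdr = None
        flags.append("no_positive_predictions")
    else:
        ppv = tp / (tp + fp)
        fdr = 1.0 - ppv
    return BinaryMetrics(tp, fp, tn, fn, sens, spec, ppv, fdr, flags)


DEFAULT_SITE_GROUPING = {
    "colorectal": "abdominal", "pancreatic": "abdominal",
    "breast": "hormonal", "prostate": "hormonal",
}


def site_grouping_task(
    features: pd.DataFrame,
    labels: pd.DataFrame,
    channels: list[str],
    grouping: dict[str, str] | None = None,
    exclude: tuple[str, ...] = ("healthy",),
    config: SubspaceEnsembleConfig | None = None,
    plan: CVPlan = CVPlan(),
) -> dict:
    """Coarse tumour-site classification (e.g. abdominal vs hormonal).

    Maps cancer-type labels through ``grouping`` (unmapped labels outside
    ``exclude`` are an error), then cross-validates a random-subspace
    ensemble with nearest-neighbour base learners.  Returns per-group
    accuracy, the confusion matrix, and the CVResult.
    """
    grouping = grouping or DEFAULT_SITE_GROUPING
    lab = labels.copy()
    lab = lab[~lab["label"].isin(exclude)]
    unmapped = set(lab["label"]) - set(grouping)
    if unmapped:
        raise ClassifyError(f"labels without site grouping: {sorted(unmapped)}")
    lab["label"] = lab["label"].map(grouping)
    feats = features[features["sample_id"].isin(lab["sample_id"])]
    if config is None:
        config = SubspaceEnsembleConfig(base="knn", n_dims=len(channels))
    result = crossvalidate(
        feats, lab, channels, lambda: SubspaceEnsemble(config), plan
    )
    sc = result.scores
    confusion = pd.crosstab(sc["label"], sc["prediction"])
    per_group = {
        g: float((sc.loc[sc["label"] == g, "prediction"] == g).mean())
        for g in sorted(sc["label"].unique())
    }
    overall = float((sc["label"] == sc["prediction"]).mean())
    return {"accuracy": overall, "per_group_accuracy": per_group,
            "confusion": confusion, "cv": result}
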