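"""One-against-all SVM classification, CV scoring, HDE tuning, and PCA.

The multiclass model is a composition of per-class soft-margin RBF
binary classifiers (class vs rest); prediction is the argmax of the
per-class decision scores, with ties broken by class order.  Model
selection minimizes 1 - mean stratified 5-fold CV accuracy over
(log2 C, log2 gamma) in [-5, 15] x [-15, 3] using the HDE optimizer.
Scaling statistics are refitted inside every training fold so no
validation row ever leaks into the model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.metrics import confusion_matrix, precision_recall_fscore_support, roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .hde import HDEConfig, OptimizeResult, optimize

__all__ = [
    "OAASVMModel",
    "CVResult",
    "EvalReport",
    "PCAResult",
    "DEFAULT_SEARCH_BOUNDS",
    "DecisionFusionModel",
    "train_decision_fusion",
    "train_oaa_svm",
    "cv_score",
    "tune_hyperparameters",
    "evaluate",
    "pca_scores",
]

#: (log2 C, log2 gamma) search box for hyperparameter tuning.
DEFAULT_SEARCH_BOUNDS = ((-5.0, 15.0), (-15.0, 3.0))


@dataclass
class OAASVMModel:
    """One binary RBF SVM per class; argmax-of-scores prediction."""

    classes_: np.ndarray
    models: dict = field(default_factory=dict)
    C: float = 1.0
    gamma: float | str = "scale"

    def decision_scores(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        return np.column_stack([self.models[c].decision_function(X) for c in self.classes_])

    def predict(self, X) -> np.ndarray:
        scores = self.decision_scores(X)
        return self.classes_[np.argmax(scores, axis=1)]


@dataclass
class CVResult:
    fold_accuracies: np.ndarray
    fold_assignment: np.ndarray

    @property
    def mean(self) -> float:
        return float(np.mean(self.fold_accuracies))

    @property
    def sd(self) -> float:
        return float(np.std(self.fold_accuracies, ddof=1))


@dataclass
class EvalReport:
    classes_: np.ndarray
    confusion: np.ndarray
    accuracy: float
    macro_precision: float
    macro_recall: float
    macro_f1: float
    auc_per_class: dict


@dataclass
class PCAResult:
    scores: np.ndarray
    explained_variance_ratio: np.ndarray
    loadings: np.ndarray


def train_oaa_svm(X, y, C: float = 1.0, gamma: float | str = "scale") -> OAASVMModel:
    """Fit the one-against-all composition on (already scaled) data."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("need at least two classes")
    if np.any(counts < 2):
        raise ValueError("every class needs at least two samples")
    model = OAASVMModel(classes_=classes, C=C, gamma=gamma)
    for c in classes:
        binary = SVC(kernel="rbf", C=C, gamma=gamma)
        binary.fit(X, (y == c).astype(int))
        model.models[c] = binary
    return model


def cv_score(
    X, y, C: float = 1.0, gamma: float | str = "scale", k: int = 5, rng: int = 0
) -> CVResult:
    """Stratified k-fold CV accuracy; scaler refitted per training fold."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    _, counts = np.unique(y, return_counts=True)
    if np.any(counts < k):
        raise ValueError(f"every class needs at least {k} members for {k}-fold CV")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=int(rng))
    accuracies = []
    assignment = np.empty(len(y), dtype=int)
    for fold, (train_idx, val_idx) in enumerate(skf.split(X, y)):
        assignment[val_idx] = fold
        mu = X[train_idx].mean(axis=0)
        sd = X[train_idx].std(axis=0)
        sd[sd == 0] = 1.0
        model = train_oaa_svm((X[train_idx] - mu) / sd, y[train_idx], C, gamma)
        pred = model.predict((X[val_idx] - mu) / sd)
        accuracies.append(float(np.mean(pred == y[val_idx])))
    return CVResult(np.array(accuracies), assignment)


def tune_hyperparameters(
    X,
    y,
    hde_config: HDEConfig | None = None,
    seed: int = 0,
    k: int = 5,
) -> tuple[float, float, CVResult, OptimizeResult]:
    """HDE search for (C, gamma) minimizing 1 - mean k-fold CV accuracy.

    Returns the decoded best parameters, the CV result at the optimum,
    and the full optimizer result (with history).
    """
    if hde_config is None:
        hde_config = HDEConfig(bounds=DEFAULT_SEARCH_BOUNDS, seed=seed)
    elif hde_config.bounds is None:
        raise ValueError("hde_config must define search bounds")

    def objective(v: np.ndarray) -> float:
        C = 2.0 ** v[0]
        gamma = 2.0 ** v[1]
        return 1.0 - cv_score(X, y, C, gamma, k=k, rng=seed).mean

    result = optimize(objective, hde_config)
    C_best = 2.0 ** result.x[0]
    gamma_best = 2.0 ** result.x[1]
    cv = cv_score(X, y, C_best, gamma_best, k=k, rng=seed)
    return C_best, gamma_best, cv, result


def evaluate(model: OAASVMModel, X_val, y_val) -> EvalReport:
    """Confusion matrix, accuracy, macro P/R/F1 and per-class OvR AUC."""
    y_val = np.asarray(y_val)
    unknown = set(np.unique(y_val)) - set(model.classes_)
    if unknown:
        raise ValueError(f"validation labels not seen at fit: {sorted(unknown)}")
    scores = model.decision_scores(X_val)
    pred = model.classes_[np.argmax(scores, axis=1)]
    cm = confusion_matrix(y_val, pred, labels=model.classes_)
    precision, recall, f1, _ = precision_recall_fscore_support(
        y_val, pred, labels=model.classes_, average="macro", zero_division=0
    )
    auc = {}
    for j, c in enumerate(model.classes_):
        positives = (y_val == c).astype(int)
        if positives.min() == positives.max():
            auc[c] = float("nan")  # class absent from validation set
        else:
            auc[c] = float(roc_auc_score(positives, scores[:, j]))
    return EvalReport(
        classes_=model.classes_,
        confusion=cm,
        accuracy=float(np.mean(pred == y_val)),
        macro_precision=float(precision),
        macro_recall=float(recall),
        macro_f1=float(f1),
        auc_per_class=auc,
    )


@dataclass
class DecisionFusionModel:
    """Per-source OAA models combined by averaging decision scores."""

    models: dict
    blocks: dict
    classes_: np.ndarray

    def decision_scores(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        stacked = [self.models[name].decision_scores(X[:, sl]) for name, sl in self.blocks.items()]
        return np.mean(stacked, axis=0)

    def predict(self, X) -> np.ndarray:
        return self.classes_[np.argmax(self.decision_scores(X), axis=1)]


def train_decision_fusion(dataset, C: float = 1.0, gamma: float | str = "scale") -> DecisionFusionModel:
    """Train one OAA SVM per fused block (decision-level fusion)."""
    models = {
        name: train_oaa_svm(dataset.X[:, sl], dataset.y, C, gamma)
        for name, sl in dataset.blocks.items()
    }
    classes = next(iter(models.values())).classes_
    return DecisionFusionModel(models=models, blocks=dict(dataset.blocks), classes_=classes)


def pca_scores(X, n_components: int = 2) -> PCAResult:
    """Principal-component scores from the column-centered covariance."""
    X = np.asarray(X, dtype=float)
    max_rank = min(X.shape)
    if n_components > max_rank:
        raise ValueError("n_components exceeds the matrix rank bound")
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(X)
    return PCAResult(
        scores=scores,
        explained_variance_ratio=pca.explained_variance_ratio_,
        loadings=pca.components_.T,
    )
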