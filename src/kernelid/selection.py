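"""Feature ranking and selection: RFE, ReliefF, and binned mutual information.

The downstream pipeline pins the five canonical image features
(``v_mean, s_dev, a_dev, r, E``); these operations reproduce the
selection methodology on synthetic data.  RFE wraps a linear max-margin
ranker; ReliefF is the standard multi-class k-nearest-hit/miss weighting;
MI is estimated from equal-width discretization and reported in bits.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.feature_selection import RFE
from sklearn.svm import LinearSVC

__all__ = ["SelectionResult", "rfe_select", "relieff_weights", "mi_scores"]


@dataclass
class SelectionResult:
    method: str
    ranking: list[str]          # best first
    selected: list[str]
    scores: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not set(self.selected) <= set(self.ranking):
            raise ValueError("selected features must appear in the ranking")


def _as_matrix(X) -> tuple[np.ndarray, list[str]]:
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float), list(X.columns)
    X = np.asarray(X, dtype=float)
    return X, [f"f{i}" for i in range(X.shape[1])]


def rfe_select(X, y, n_select: int, step: int = 1, C: float = 1.0) -> SelectionResult:
    """Recursive feature elimination with a linear one-vs-rest SVM ranker.

    At each round the ``step`` features with the smallest aggregate
    |weight| are removed; the full elimination order is recorded in
    ``ranking`` (surviving features first, then by reverse elimination).
    """
    Xm, names = _as_matrix(X)
    if n_select > Xm.shape[1]:
        raise ValueError("n_select exceeds the number of features")
    if np.all(Xm.std(axis=0) == 0):
        raise ValueError("all features are constant; RFE ranking is undefined")
    estimator = LinearSVC(C=C, dual=True, max_iter=20000, random_state=0)
    rfe = RFE(estimator, n_features_to_select=n_select, step=step)
    rfe.fit(Xm, y)
    order = np.argsort(rfe.ranking_, kind="stable")
    ranking = [names[i] for i in order]
    selected = [names[i] for i in np.flatnonzero(rfe.support_)]
    scores = {names[i]: float(-rfe.ranking_[i]) for i in range(len(names))}
    return SelectionResult("RFE", ranking, selected, scores)


def relieff_weights(
    X, y, k_neighbors: int = 10, m_samples: int | None = None, rng=None,
    n_select: int | None = None,
) -> SelectionResult:
    """Multi-class ReliefF relevance weights.

    For each sampled instance, every feature weight is decreased by the
    mean distance to the k nearest same-class hits and increased by the
    prior-weighted mean distance to the k nearest misses of each other
    class.  Features are min-max scaled internally so distances are
    comparable.
    """
    Xm, names = _as_matrix(X)
    y = np.asarray(y)
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    n, d = Xm.shape
    classes, counts = np.unique(y, return_counts=True)
    if np.any(counts < k_neighbors + 1):
        raise ValueError("every class needs at least k_neighbors + 1 members")
    span = Xm.max(axis=0) - Xm.min(axis=0)
    span[span == 0] = 1.0
    Xs = (Xm - Xm.min(axis=0)) / span
    priors = {c: cnt / n for c, cnt in zip(classes, counts)}

    if m_samples is None or m_samples >= n:
        sample_idx = np.arange(n)
    else:
        sample_idx = rng.choice(n, size=m_samples, replace=False)

    weights = np.zeros(d)
    for i in sample_idx:
        xi = Xs[i]
        dist = np.abs(Xs - xi).sum(axis=1)  # L1, standard for ReliefF
        for c in classes:
            members = np.flatnonzero(y == c)
            if c == y[i]:
                members = members[members != i]
            nearest = members[np.argsort(dist[members], kind="stable")[:k_neighbors]]
            mean_diff = np.abs(Xs[nearest] - xi).mean(axis=0)
            if c == y[i]:
                weights -= mean_diff
            else:
                weights += priors[c] / (1.0 - priors[y[i]]) * mean_diff
    weights /= len(sample_idx)
    order = np.argsort(-weights, kind="stable")
    ranking = [names[i] for i in order]
    k = n_select if n_select is not None else len(names)
    return SelectionResult(
        "ReliefF", ranking, ranking[:k], dict(zip(names, weights.astype(float)))
    )


def mi_scores(X, y, n_bins: int = 10, n_select: int | None = None) -> SelectionResult:
    """Mutual information (bits) between equal-width-binned features and labels."""
    if n_bins < 2:
        raise ValueError("n_bins must be at least 2")
    Xm, names = _as_matrix(X)
    y = np.asarray(y)
    n = len(y)
    _, y_codes = np.unique(y, return_inverse=True)
    scores = {}
    for j, name in enumerate(names):
        col = Xm[:, j]
        lo, hi = col.min(), col.max()
        if hi == lo:
            scores[name] = 0.0
            continue
        bins = np.clip(((col - lo) / (hi - lo) * n_bins).astype(int), 0, n_bins - 1)
        joint = np.zeros((n_bins, y_codes.max() + 1))
        np.add.at(joint, (bins, y_codes), 1.0)
        joint /= n
        px = joint.sum(axis=1, keepdims=True)
        py = joint.sum(axis=0, keepdims=True)
        nz = joint > 0
        scores[name] = float(
            (joint[nz] * np.log2(joint[nz] / (px @ py)[nz])).sum()
        )
    order = sorted(names, key=lambda nm: -scores[nm])
    k = n_select if n_select is not None else len(names)
    return SelectionResult("MI", order, order[:k], scores)
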