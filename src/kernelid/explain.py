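"""Shapley-value attribution for the trained classifier.

A feature's Shapley value is its average marginal contribution to the
model's per-class decision score over all orderings of the features.
The sampler estimates it by Monte-Carlo over random feature orderings,
with absent features drawn from a background sample; the exact
enumerator (tractable up to ~12 features) serves as an oracle and for
small models.  Attributions are in the units of the decision score and
satisfy local accuracy: sum_j phi_jc + base_c ~= score_c(x).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import factorial

import numpy as np
import pandas as pd

__all__ = [
    "Attribution",
    "shapley_attributions",
    "exact_shapley",
    "summary_importance",
    "dependence_data",
]


@dataclass
class Attribution:
    """Per-feature, per-class Shapley values for one instance."""

    phi: np.ndarray          # (n_features, n_classes)
    base_value: np.ndarray   # (n_classes,)
    x: np.ndarray
    feature_names: list[str] | None = None


def _scores_2d(score_fn, X: np.ndarray) -> np.ndarray:
    out = np.asarray(score_fn(X), dtype=float)
    if out.ndim == 1:
        out = out[:, None]
    if not np.all(np.isfinite(out)):
        raise ValueError("score function returned non-finite values")
    return out


def shapley_attributions(
    score_fn,
    x,
    background,
    n_permutations: int = 2000,
    rng=None,
    feature_names=None,
) -> Attribution:
    """Permutation-sampling Shapley estimate.

    For each sampled ordering, one background row is drawn; features are
    switched from the background value to the instance value in order,
    and each feature is credited with the score change it causes.  The
    base value is the mean score over the full background.
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be at least 1")
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    x = np.asarray(x, dtype=float)
    background = np.atleast_2d(np.asarray(background, dtype=float))
    if background.shape[0] == 0:
        raise ValueError("background must be non-empty")
    d = x.size
    base = _scores_2d(score_fn, background).mean(axis=0)
    n_classes = base.size
    phi = np.zeros((d, n_classes))

    for _ in range(n_permutations):
        order = rng.permutation(d)
        b = background[rng.integers(background.shape[0])]
        # d+1 states: background, then one feature flipped at a time
        states = np.tile(b, (d + 1, 1))
        for step, j in enumerate(order, start=1):
            states[step:, j] = x[j]
        scores = _scores_2d(score_fn, states)
        deltas = np.diff(scores, axis=0)  # (d, n_classes), in flip order
        phi[order] += deltas
    phi /= n_permutations
    return Attribution(phi=phi, base_value=base, x=x,
                       feature_names=list(feature_names) if feature_names else None)


def exact_shapley(
    score_fn, x, background_mean, max_features: int = 12, feature_names=None
) -> Attribution:
    """Exact Shapley values by coalition enumeration.

    Absent features take the background-mean value.  Exactly satisfies
    the efficiency axiom: sum_j phi_j = score(x) - score(background_mean).
    """
    x = np.asarray(x, dtype=float)
    b = np.asarray(background_mean, dtype=float)
    d = x.size
    if d > max_features:
        raise ValueError(f"exact enumeration limited to {max_features} features")
    n_coalitions = 1 << d
    states = np.tile(b, (n_coalitions, 1))
    for mask in range(n_coalitions):
        for j in range(d):
            if mask >> j & 1:
                states[mask, j] = x[j]
    values = _scores_2d(score_fn, states)
    n_classes = values.shape[1]
    phi = np.zeros((d, n_classes))
    fact = [factorial(k) for k in range(d + 1)]
    for j in range(d):
        others = [k for k in range(d) if k != j]
        for size in range(d):
            weight = fact[size] * fact[d - size - 1] / fact[d]
            for subset in combinations(others, size):
                mask = sum(1 << k for k in subset)
                phi[j] += weight * (values[mask | (1 << j)] - values[mask])
    return Attribution(phi=phi, base_value=values[0], x=x,
                       feature_names=list(feature_names) if feature_names else None)


def summary_importance(attributions: list[Attribution]) -> pd.DataFrame:
    """Mean |phi| per feature per class over a set of attributions."""
    if not attributions:
        raise ValueError("need at least one attribution")
    stacked = np.stack([np.abs(a.phi) for a in attributions])  # (n, d, k)
    mean_abs = stacked.mean(axis=0)
    names = attributions[0].feature_names or [
        f"f{i}" for i in range(mean_abs.shape[0])
    ]
    frame = pd.DataFrame(
        mean_abs, index=names, columns=[f"class{j}" for j in range(mean_abs.shape[1])]
    )
    frame["overall"] = mean_abs.mean(axis=1)
    return frame.sort_values("overall", ascending=False)


def dependence_data(
    attributions: list[Attribution],
    X,
    feature: int,
    class_index: int,
    color_feature: int | None = None,
) -> pd.DataFrame:
    """Feature value vs Shapley value, with an optional coloring feature."""
    X = np.asarray(X, dtype=float)
    if len(attributions) != X.shape[0]:
        raise ValueError("attributions and X rows must align")
    out = pd.DataFrame(
        {
            "value": X[:, feature],
            "phi": [a.phi[feature, class_index] for a in attributions],
        }
    )
    if color_feature is not None:
        out["color_value"] = X[:, color_feature]
    return out
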