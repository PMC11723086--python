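"""Multi-source fusion of NMR and image feature blocks.

Three levels are supported: *feature*-level fusion (the pipeline default)
concatenates the 10 decay-curve features with the 5 selected image
features into a 15-column design; *data*-level fusion concatenates raw
blocks as given (e.g. the full echo train with all image features);
*decision*-level fusion keeps the blocks separate so per-source
classifiers can be combined at predict time.  Scaling statistics are
always fitted on training rows only and applied everywhere.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "FusedDataset",
    "ColumnScaler",
    "aggregate_image_per_sample",
    "fuse",
    "fit_scaler",
    "apply_scaler",
    "train_val_split",
]


@dataclass
class ColumnScaler:
    """Per-column z-score state (location/scale from training rows only)."""

    mean: np.ndarray
    scale: np.ndarray

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, dtype=float) - self.mean) / self.scale


@dataclass
class FusedDataset:
    """Labeled feature matrix with named columns and block provenance."""

    X: np.ndarray
    feature_names: list[str]
    y: np.ndarray
    fusion_level: str
    blocks: dict[str, slice] = field(default_factory=dict)
    scaler_state: ColumnScaler | None = None

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y)
        if self.X.shape[1] != len(self.feature_names):
            raise ValueError("feature_names must match the number of columns")
        if self.X.shape[0] != self.y.shape[0]:
            raise ValueError("X and y row counts differ")
        if not np.all(np.isfinite(self.X)):
            raise ValueError("fused matrix contains non-finite entries")

    def block(self, name: str) -> np.ndarray:
        return self.X[:, self.blocks[name]]


def aggregate_image_per_sample(
    kernel_features: pd.DataFrame,
    sample_ids,
    policy: str = "mean",
) -> pd.DataFrame:
    """Aggregate per-kernel feature rows to one row per sample.

    ``sample_ids`` assigns each kernel row to a sample; policy is "mean"
    or "median".  Raises on an empty input group.
    """
    if policy not in ("mean", "median"):
        raise ValueError("policy must be 'mean' or 'median'")
    if len(kernel_features) == 0:
        raise ValueError("no kernel rows to aggregate")
    sample_ids = np.asarray(sample_ids)
    if len(sample_ids) != len(kernel_features):
        raise ValueError("sample_ids must align with kernel rows")
    grouped = kernel_features.groupby(sample_ids, sort=True)
    return grouped.mean() if policy == "mean" else grouped.median()


def fuse(nmr_X: pd.DataFrame, image_X: pd.DataFrame, y, level: str = "feature") -> FusedDataset:
    """Combine row-aligned NMR and image blocks at the requested level.

    Feature- and data-level fusion concatenate columns (the two blocks
    can be sliced back exactly via ``blocks``); decision-level fusion
    stores the same concatenation but tags the blocks for per-source
    classification downstream.
    """
    if level not in ("data", "feature", "decision"):
        raise ValueError("level must be 'data', 'feature' or 'decision'")
    y = np.asarray(y)
    if len(nmr_X) and len(image_X) and len(nmr_X) != len(image_X):
        raise ValueError("NMR and image blocks have different row counts")
    parts, names, blocks = [], [], {}
    col = 0
    for block_name, frame in (("nmr", nmr_X), ("image", image_X)):
        if frame is None or frame.shape[1] == 0:
            continue
        parts.append(np.asarray(frame, dtype=float))
        cols = list(frame.columns)
        names.extend(cols)
        blocks[block_name] = slice(col, col + len(cols))
        col += len(cols)
    X = np.hstack(parts)
    return FusedDataset(X=X, feature_names=names, y=y, fusion_level=level, blocks=blocks)


def fit_scaler(dataset: FusedDataset, train_rows) -> ColumnScaler:
    """Z-score statistics from the training rows only."""
    train_rows = np.asarray(train_rows)
    Xtr = dataset.X[train_rows]
    if Xtr.shape[0] == 0:
        raise ValueError("train_rows selects no rows")
    mean = Xtr.mean(axis=0)
    scale = Xtr.std(axis=0)
    if np.any(scale == 0):
        warnings.warn("zero-variance column(s); scale set to 1", stacklevel=2)
        scale = np.where(scale == 0, 1.0, scale)
    return ColumnScaler(mean=mean, scale=scale)


def apply_scaler(dataset: FusedDataset, scaler: ColumnScaler) -> FusedDataset:
    """Return a copy of the dataset with all rows scaled by ``scaler``."""
    return FusedDataset(
        X=scaler.transform(dataset.X),
        feature_names=list(dataset.feature_names),
        y=dataset.y.copy(),
        fusion_level=dataset.fusion_level,
        blocks=dict(dataset.blocks),
        scaler_state=scaler,
    )


def train_val_split(y, n_train_per_class: int = 24, rng=None):
    """Stratified, seeded train/validation masks (default 24/6 per class)."""
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    y = np.asarray(y)
    train = np.zeros(len(y), dtype=bool)
    for c in np.unique(y):
        idx = np.flatnonzero(y == c)
        if len(idx) <= n_train_per_class:
            raise ValueError(f"class {c!r} has too few samples for the split")
        chosen = rng.choice(idx, size=n_train_per_class, replace=False)
        train[chosen] = True
    return train, ~train
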