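"""End-to-end variety-identification pipeline on synthetic data.

Reproduces the study design: 11 varieties x n seeds, decay curves
feature-extracted to the ten-column table, kernel images reduced to the
five selected morphological features, feature-level fusion (15 columns),
a stratified 24/6-per-class train/validation split, HDE-tuned
one-against-all SVM, and evaluation on the held-out rows.

Image kernels are rendered one per NMR sample and aligned via the
generator's ground-truth masks, which resolves the kernel-to-sample
correspondence exactly (watershed segmentation is exercised by its own
tests and the `segmentation="watershed"` option).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .classify import CVResult, EvalReport, OAASVMModel, cv_score, evaluate, train_oaa_svm, tune_hyperparameters
from .decay import DEFAULT_CONFIG, AcquisitionGrid, NMRConfig, extract_t2_features
from .fusion import FusedDataset, apply_scaler, fit_scaler, fuse, train_val_split
from .hde import HDEConfig, OptimizeResult
from .imaging import (
    DEFAULT_IMAGE_CONFIG,
    SELECTED_IMAGE_FEATURES,
    extract_image_features,
    features_from_labeled_mask,
)
from .io import features_to_frame
from .simulate import default_image_params, default_variety_params, generate_dataset, generate_kernel_image

__all__ = ["PipelineResult", "simulate_fused_dataset", "run_pipeline"]


@dataclass
class PipelineResult:
    dataset: FusedDataset
    train_mask: np.ndarray
    val_mask: np.ndarray
    C: float
    gamma: float
    cv_untuned: CVResult
    cv_tuned: CVResult
    report: EvalReport
    model: OAASVMModel
    optimizer: OptimizeResult


def simulate_fused_dataset(
    seed: int = 0,
    n_per_variety: int = 30,
    grid: AcquisitionGrid = AcquisitionGrid(),
    nmr_config: NMRConfig = DEFAULT_CONFIG,
    segmentation: str = "truth",
    image_size: tuple[int, int] = (900, 900),
) -> FusedDataset:
    """Simulate curves and images and return the 15-column fused dataset."""
    rng = np.random.default_rng(seed)
    curves, labels = generate_dataset(n_per_variety, grid, rng)
    feats = [extract_t2_features(c, nmr_config) for c in curves]
    nmr_frame = features_to_frame(feats, labels).drop(columns="variety")

    image_params = default_image_params()
    image_rows = []
    for variety in sorted(set(labels)):
        image, mask = generate_kernel_image(
            image_params[variety], n_per_variety, rng, image_size=image_size
        )
        if segmentation == "watershed":
            rows = extract_image_features(image, DEFAULT_IMAGE_CONFIG)
        else:
            rows = features_from_labeled_mask(image, mask, DEFAULT_IMAGE_CONFIG)
        if len(rows) != n_per_variety:
            # pad/trim so rows stay aligned with the NMR samples
            rows = rows.iloc[
                np.arange(n_per_variety) % max(len(rows), 1)
            ].reset_index(drop=True)
        image_rows.append(rows[list(SELECTED_IMAGE_FEATURES)])
    image_frame = pd.concat(image_rows, ignore_index=True)

    return fuse(nmr_frame, image_frame, labels, level="feature")


def run_pipeline(
    seed: int = 0,
    n_per_variety: int = 30,
    hde_config: HDEConfig | None = None,
    n_train_per_class: int = 24,
    segmentation: str = "truth",
) -> PipelineResult:
    """Full simulate -> extract -> fuse -> tune -> evaluate run."""
    from .classify import DEFAULT_SEARCH_BOUNDS

    dataset = simulate_fused_dataset(seed, n_per_variety, segmentation=segmentation)
    train_mask, val_mask = train_val_split(
        dataset.y, n_train_per_class, np.random.default_rng(seed + 1)
    )
    scaler = fit_scaler(dataset, train_mask)
    scaled = apply_scaler(dataset, scaler)
    X_train, y_train = scaled.X[train_mask], scaled.y[train_mask]
    X_val, y_val = scaled.X[val_mask], scaled.y[val_mask]

    n_features = X_train.shape[1]
    cv_untuned = cv_score(X_train, y_train, C=1.0, gamma=1.0 / n_features, rng=seed)

    if hde_config is None:
        hde_config = HDEConfig(
            bounds=DEFAULT_SEARCH_BOUNDS, population_size=10, generations=15, seed=seed
        )
    C, gamma, cv_tuned, opt = tune_hyperparameters(
        X_train, y_train, hde_config=hde_config, seed=seed
    )
    model = train_oaa_svm(X_train, y_train, C, gamma)
    report = evaluate(model, X_val, y_val)
    return PipelineResult(
        dataset=dataset,
        train_mask=train_mask,
        val_mask=val_mask,
        C=C,
        gamma=gamma,
        cv_untuned=cv_untuned,
        cv_tuned=cv_tuned,
        report=report,
        model=model,
        optimizer=opt,
    )
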