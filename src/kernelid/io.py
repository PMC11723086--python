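"""Plain-text I/O: long-format curve CSV, feature tables, parameter JSON."""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .decay import FEATURE_NAMES, DecayCurve, T2FeatureVector
from .simulate import VarietyGeneratorParams

__all__ = [
    "write_curves_csv",
    "read_curves_csv",
    "features_to_frame",
    "write_features_csv",
    "read_features_csv",
    "write_params_json",
    "read_params_json",
]


def write_curves_csv(curves: list[DecayCurve], labels: list[str], path) -> None:
    """Long format: sample_id, variety, time_ms, signal_au."""
    frames = []
    for curve, variety in zip(curves, labels):
        frames.append(
            pd.DataFrame(
                {
                    "sample_id": curve.sample_id,
                    "variety": variety,
                    "time_ms": curve.time,
                    "signal_au": curve.signal,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_curves_csv(path) -> tuple[list[DecayCurve], list[str]]:
    table = pd.read_csv(path)
    curves, labels = [], []
    for sample_id, group in table.groupby("sample_id", sort=False):
        curves.append(
            DecayCurve(
                time=group["time_ms"].to_numpy(),
                signal=group["signal_au"].to_numpy(),
                sample_id=str(sample_id),
            )
        )
        labels.append(str(group["variety"].iloc[0]))
    return curves, labels


def features_to_frame(
    features: list[T2FeatureVector], labels: list[str], sample_ids: list[str] | None = None
) -> pd.DataFrame:
    """Feature table with exactly the ten published column names."""
    frame = pd.DataFrame([f.as_dict() for f in features], columns=list(FEATURE_NAMES))
    frame.insert(0, "variety", labels)
    if sample_ids is not None:
        frame.insert(0, "sample_id", sample_ids)
    return frame


def write_features_csv(features, labels, path, sample_ids=None) -> None:
    features_to_frame(features, labels, sample_ids).to_csv(path, index=False)


def read_features_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_params_json(params: dict[str, VarietyGeneratorParams], path) -> None:
    payload = {name: asdict(p) for name, p in params.items()}
    Path(path).write_text(json.dumps(payload, indent=2))


def read_params_json(path) -> dict[str, VarietyGeneratorParams]:
    payload = json.loads(Path(path).read_text())
    return {
        name: VarietyGeneratorParams(
            variety_id=entry["variety_id"],
            amplitudes=tuple(entry["amplitudes"]),
            time_constants=tuple(entry["time_constants"]),
            noise_sd=entry.get("noise_sd", 0.0),
            amp_jitter=entry.get("amp_jitter", 0.0),
            tau_jitter=entry.get("tau_jitter", 0.0),
        )
        for name, entry in payload.items()
    }
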