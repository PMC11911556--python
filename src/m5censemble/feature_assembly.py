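"""Assembly of the per-window feature vector and train-fit standardization.

Pinned composition (434 features):

==========================================  =====
block                                       width
==========================================  =====
sequence-matrix moments (raw|central|Hahn)     30
PRIM mono, raw 4x4 entries                     16
PRIM di, 30-coefficient moment reduction       30
PRIM tri, 30-coefficient moment reduction      30
RPRIM mono / di / tri (as above)               76
FV mono + di + tri                             84
AAPIV mono + di + tri                          84
RAAPIV mono + di + tri                         84
==========================================  =====
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from . import position_features as pf
from .moments import MomentConfig, moment_descriptor, to_matrix
from .seq_io import LabeledDataset, SequenceWindow, encode_numeric

TOTAL_FEATURES = 434


@dataclass(frozen=True)
class FeatureVector:
    """A named, fixed-order numeric description of one window."""

    values: np.ndarray
    names: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.values) != len(self.names):
            raise ValueError("values and names differ in length")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature vector contains non-finite values")


def _moment_names(prefix: str, cfg: MomentConfig) -> list[str]:
    return [
        f"{prefix}_{family}_{u}{v}"
        for family in ("raw", "central", "hahn")
        for u, v in cfg.orders
    ]


def feature_names(cfg: MomentConfig = MomentConfig()) -> tuple[str, ...]:
    """The pinned, stable feature-column names."""
    names: list[str] = _moment_names("seq", cfg)
    names += [f"prim1_r{i}c{j}" for i in range(1, 5) for j in range(1, 5)]
    names += _moment_names("prim2_mom", cfg)
    names += _moment_names("prim3_mom", cfg)
    names += [f"rprim1_r{i}c{j}" for i in range(1, 5) for j in range(1, 5)]
    names += _moment_names("rprim2_mom", cfg)
    names += _moment_names("rprim3_mom", cfg)
    for block in ("fv", "aapiv", "raapiv"):
        for k in (1, 2, 3):
            names += [f"{block}{k}_{kmer}" for kmer in pf.kmer_alphabet(k)]
    return tuple(names)


def assemble(
    window: SequenceWindow | str, cfg: MomentConfig = MomentConfig()
) -> FeatureVector:
    """Compute the full 434-feature vector of one valid window."""
    blocks = [moment_descriptor(to_matrix(encode_numeric(window)), cfg).values]
    for source in (pf.prim, pf.rprim):
        blocks.append(source(window, 1).ravel().astype(float))
        blocks.append(pf.reduce_matrix(source(window, 2), cfg))
        blocks.append(pf.reduce_matrix(source(window, 3), cfg))
    for extractor in (pf.frequency_vector, pf.aapiv, pf.raapiv):
        for k in (1, 2, 3):
            blocks.append(extractor(window, k).astype(float))
    values = np.concatenate(blocks)
    return FeatureVector(values=values, names=feature_names(cfg))


def assemble_dataset(
    dataset: LabeledDataset | Sequence[SequenceWindow],
    cfg: MomentConfig = MomentConfig(),
) -> tuple[np.ndarray, tuple[str, ...]]:
    """Feature matrix (n_windows x 434) plus column names."""
    windows = list(dataset)
    names = feature_names(cfg)
    X = np.empty((len(windows), len(names)))
    for row, window in enumerate(windows):
        X[row] = assemble(window, cfg).values
    return X, names


@dataclass(frozen=True)
class ScalerState:
    """Per-feature standardization statistics learned from training rows.

    Zero-variance features keep scale 1 (mean-centering only), so
    constant columns map to exactly 0.
    """

    mean: np.ndarray
    scale: np.ndarray
    names: tuple[str, ...]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "mean": self.mean.tolist(),
            "scale": self.scale.tolist(),
            "names": list(self.names),
        }
        Path(path).write_text(json.dumps(payload), encoding="utf-8")

    @classmethod
    def from_json(cls, path: str | Path) -> "ScalerState":
        payload = json.loads(Path(path).read_text(encoding="utf-8"))
        return cls(
            mean=np.array(payload["mean"]),
            scale=np.array(payload["scale"]),
            names=tuple(payload["names"]),
        )


def fit_scaler(
    train: np.ndarray, names: Sequence[str] | None = None
) -> ScalerState:
    """Learn z-score statistics from training rows only."""
    train = np.asarray(train, dtype=float)
    if train.ndim != 2 or train.shape[0] < 2:
        raise ValueError("scaler requires at least 2 training rows")
    mean = train.mean(axis=0)
    scale = train.std(axis=0)
    scale[scale == 0.0] = 1.0
    if names is None:
        names = [f"f{i}" for i in range(train.shape[1])]
    return ScalerState(mean=mean, scale=scale, names=tuple(names))


def apply_scaler(state: ScalerState, X: np.ndarray) -> np.ndarray:
    """Standardize rows with training statistics (train and test alike)."""
    X = np.asarray(X, dtype=float)
    if X.shape[1] != state.mean.size:
        raise ValueError(
            f"expected {state.mean.size} features, got {X.shape[1]}"
        )
    return (X - state.mean) / state.scale
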