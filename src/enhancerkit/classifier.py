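"""RBF-kernel SVM training, grid search and the two-layer prediction cascade.

Layer I decides enhancer versus non-enhancer; layer II, consulted only for
sequences layer I called positive, decides strong versus weak enhancer.
Each layer carries its own selected feature set and its own bi-profile
Bayes model, because the two tasks are driven by different sequence
signals.

Default hyperparameters are the published operating points of the method
this package implements: ``C = 0.35355`` (2^-1.5) for both layers, with
``gamma = 0.03125`` (2^-5) for layer I and ``gamma = 1.4142`` (2^0.5) for
layer II.  The grid-search lattice is the conventional powers-of-two grid
(exponents -8 ... 8 in steps of 0.5) on which all three values lie.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.svm import SVC

from .encoders import BPBModel, FeatureMatrix, encode_dataset
from .sequence_io import (
    NON_ENHANCER,
    STRONG_ENHANCER,
    WEAK_ENHANCER,
    LayeredDataset,
    SequenceRecord,
)

#: Powers-of-two lattice used for (C, gamma) search.
DEFAULT_GRID: tuple[float, ...] = tuple(
    float(2.0**e) for e in np.arange(-8, 8.5, 0.5)
)


@dataclass(frozen=True)
class SvmConfig:
    """RBF-SVM hyperparameters and grid-search settings."""

    C: float = 0.35355
    gamma: float = 0.03125
    cv_folds: int = 15
    C_grid: tuple[float, ...] = DEFAULT_GRID
    gamma_grid: tuple[float, ...] = DEFAULT_GRID
    class_weight: dict | None = None
    rescale: bool = False

    def __post_init__(self) -> None:
        if self.C <= 0 or self.gamma <= 0:
            raise ValueError("C and gamma must be positive")


LAYER1_SVM = SvmConfig(C=0.35355, gamma=0.03125)
LAYER2_SVM = SvmConfig(C=0.35355, gamma=1.4142)


class TrainedSvm:
    """A fitted binary RBF-SVM exposing predictions and decision values."""

    def __init__(self, svc: SVC, lo: np.ndarray | None, span: np.ndarray | None):
        self._svc = svc
        self._lo = lo
        self._span = span

    def _transform(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if self._lo is None:
            return X
        return (X - self._lo) / self._span

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self._svc.predict(self._transform(X))

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        return self._svc.decision_function(self._transform(X))


def train_svm(
    X: np.ndarray, y: Sequence[int], config: SvmConfig
) -> TrainedSvm:
    """Fit an RBF-SVM on a feature matrix with +1/-1 labels.

    Deterministic for fixed config and data order.  Feature rescaling is
    off by default: the BPB/NC/PseNC families are already frequencies in
    [0, 1].  ``config.rescale`` enables per-feature min-max scaling for
    user-supplied feature families on other scales.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if X.ndim != 2 or X.shape[0] != len(y):
        raise ValueError("X must be 2-D with one row per label")
    if not np.isfinite(X).all():
        raise ValueError("feature matrix contains non-finite values")
    if len(np.unique(y)) < 2:
        raise ValueError("training requires samples from both classes")
    lo = span = None
    if config.rescale:
        lo = X.min(axis=0)
        span = X.max(axis=0) - lo
        span[span == 0] = 1.0
        X = (X - lo) / span
    svc = SVC(
        kernel="rbf",
        C=config.C,
        gamma=config.gamma,
        class_weight=config.class_weight,
        cache_size=256,
    )
    svc.fit(X, y)
    return TrainedSvm(svc, lo, span)


def grid_search(
    X: np.ndarray,
    y: Sequence[int],
    config: SvmConfig | None = None,
    *,
    cv_folds: int | None = None,
    seed: int = 0,
) -> SvmConfig:
    """Pick (C, gamma) maximising mean cross-validated accuracy.

    Folds are seeded and stratified; ties resolve to the smaller C, then
    the smaller gamma, so the result is deterministic.
    """
    from .evaluation import build_folds  # deferred: avoids cycle

    config = config or SvmConfig()
    k = cv_folds if cv_folds is not None else config.cv_folds
    y = np.asarray(y)
    X = np.asarray(X, dtype=float)
    if k < 2:
        raise ValueError("cv_folds must be at least 2")
    for cls in (1, -1):
        if int(np.sum(y == cls)) < k:
            raise ValueError("each class needs at least cv_folds members")
    folds = build_folds(y, k, seed)
    best: tuple[float, float, float] | None = None  # (acc, C, gamma)
    from .evaluation import _evaluate_matrix_folds

    for C in sorted(config.C_grid):
        for gamma in sorted(config.gamma_grid):
            cand = replace(config, C=C, gamma=gamma)
            metrics, _ = _evaluate_matrix_folds(X, y, folds, cand)
            acc = metrics.acc
            if best is None or acc > best[0] + 1e-12:
                best = (acc, C, gamma)
    assert best is not None
    return replace(config, C=best[1], gamma=best[2])


@dataclass
class LayerModel:
    """One cascade layer: its SVM, feature names and BPB profiles."""

    svm: TrainedSvm
    feature_names: list[str]
    bpb: BPBModel | None
    families: tuple[str, ...]
    config: SvmConfig


@dataclass
class TwoLayerModel:
    """The enhancer-vs-non-enhancer and strong-vs-weak cascade."""

    layer1: LayerModel
    layer2: LayerModel


@dataclass(frozen=True)
class Prediction:
    """Cascade output for one sequence.

    ``layer2_score`` is None when layer I called the sequence a
    non-enhancer, in which case layer II is never consulted.
    """

    id: str
    label: str
    layer1_score: float
    layer2_score: float | None


def _encode_layer(layer: LayerModel, records: Sequence[SequenceRecord]) -> np.ndarray:
    matrix = encode_dataset(records, bpb=layer.bpb, families=layer.families)
    return matrix.subset(layer.feature_names).values


def train_two_layer(
    dataset: LayeredDataset,
    layer1_features: Sequence[str],
    layer2_features: Sequence[str],
    *,
    config1: SvmConfig = LAYER1_SVM,
    config2: SvmConfig = LAYER2_SVM,
    families: Sequence[str] = ("BPB", "NC", "PseNC"),
    alpha: float = 0.0,
) -> TwoLayerModel:
    """Fit both cascade layers on a three-class dataset.

    Each layer fits its own BPB model on its own positive/negative split,
    encodes its sequences, restricts to its selected feature names and
    trains its SVM.
    """
    from .encoders import fit_bpb

    layers = []
    for layer_name, feats, config in (
        ("I", layer1_features, config1),
        ("II", layer2_features, config2),
    ):
        if layer_name == "I":
            records, y = dataset.layer1()
        else:
            records, y = dataset.layer2()
        pos = [r for r, yy in zip(records, y) if yy > 0]
        neg = [r for r, yy in zip(records, y) if yy < 0]
        fams = tuple(families)
        bpb = fit_bpb(pos, neg, dataset.n, alpha=alpha) if "BPB" in fams else None
        matrix = encode_dataset(records, bpb=bpb, families=fams)
        X = matrix.subset(list(feats)).values
        svm = train_svm(X, y, config)
        layers.append(
            LayerModel(
                svm=svm,
                feature_names=list(feats),
                bpb=bpb,
                families=fams,
                config=config,
            )
        )
    return TwoLayerModel(layer1=layers[0], layer2=layers[1])


def predict_two_layer(
    model: TwoLayerModel, records: Sequence[SequenceRecord]
) -> list[Prediction]:
    """Run the cascade: layer I gates, layer II grades the positives."""
    records = list(records)
    if not records:
        return []
    X1 = _encode_layer(model.layer1, records)
    s1 = model.layer1.svm.decision_function(X1)
    enhancer_mask = s1 > 0
    out: list[Prediction | None] = [None] * len(records)
    if enhancer_mask.any():
        idx = np.flatnonzero(enhancer_mask)
        X2 = _encode_layer(model.layer2, [records[i] for i in idx])
        s2 = model.layer2.svm.decision_function(X2)
        for j, i in enumerate(idx):
            label = STRONG_ENHANCER if s2[j] > 0 else WEAK_ENHANCER
            out[i] = Prediction(records[i].id, label, float(s1[i]), float(s2[j]))
    for i in np.flatnonzero(~enhancer_mask):
        out[i] = Prediction(records[i].id, NON_ENHANCER, float(s1[i]), None)
    return [p for p in out if p is not None]


def save_model(model: TwoLayerModel, path: str | Path) -> None:
    """Persist a trained cascade as a single joblib bundle."""
    import joblib

    joblib.dump({"format": "enhancerkit-two-layer-v1", "model": model}, path)


def load_model(path: str | Path) -> TwoLayerModel:
    import joblib

    bundle = joblib.load(path)
    if bundle.get("format") != "enhancerkit-two-layer-v1":
        raise ValueError(f"{path}: not an enhancerkit model bundle")
    return bundle["model"]
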