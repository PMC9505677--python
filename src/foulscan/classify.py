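"""Per-pixel wide-neural-network classification of calibrated hypercubes.

The classifier is a single-hidden-layer network of 100 ReLU units with no
L2 penalty, trained on standardized inputs by a quasi-Newton optimizer
(L-BFGS) with seeded initialization — the standard shallow "wide" network
for spectral-library classification.  Inputs are either the raw channel
spectra or, by default, their projection onto the principal components
explaining 99.99% of the training variance, which shortens training and
curbs overfitting.  Prediction is purely per-pixel: each valid pixel's
spectrum is projected with the stored transform and assigned the argmax
class; masked pixels receive the invalid code.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import StratifiedKFold
from sklearn.neural_network import MLPClassifier
from sklearn.preprocessing import StandardScaler

from . import pca as _pca
from .calibrate import ReflectanceCube
from .hsio import LabelMap
from .library import SpectralLibrary

__all__ = ["WNNConfig", "WNNModel", "PredictionMap", "train", "cross_validate", "predict_cube"]


@dataclass(frozen=True)
class WNNConfig:
    hidden_units: int = 100
    l2_regularization: float = 0.0
    standardize_inputs: bool = True
    cv_folds: int = 5
    use_pca: bool = True
    pca_threshold_pct: float = 99.99
    seed: int = 0
    max_iterations: int = 400
    tol: float = 1e-6

    def __post_init__(self):
        if self.hidden_units < 1:
            raise ValueError("hidden_units must be >= 1")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")


@dataclass
class WNNModel:
    """Trained network plus the frozen input transform."""

    net: MLPClassifier
    scaler: StandardScaler | None
    pca_model: _pca.PCAModel | None
    classes: list[str]
    config: WNNConfig
    cv_accuracy_pct: float | None = None
    grid_centers: np.ndarray | None = None

    def transform(self, spectra: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(spectra, dtype=float))
        if self.pca_model is not None:
            X = _pca.project(X, self.pca_model)
        if self.scaler is not None:
            X = self.scaler.transform(X)
        return X

    def predict(self, spectra: np.ndarray) -> np.ndarray:
        """Hard labels; softmax-score ties break toward the lowest class index."""
        scores = self.predict_scores(spectra)
        idx = scores.argmax(axis=1)  # argmax returns the first (lowest) index on ties
        return np.array(self.classes)[idx]

    def predict_scores(self, spectra: np.ndarray) -> np.ndarray:
        return self.net.predict_proba(self.transform(spectra))


@dataclass
class PredictionMap:
    """Predicted class raster; masked pixels carry the invalid code 0."""

    label_map: LabelMap
    scores: np.ndarray | None = None

    @property
    def shape(self):
        return self.label_map.shape


def _make_net(config: WNNConfig) -> MLPClassifier:
    return MLPClassifier(
        hidden_layer_sizes=(config.hidden_units,),
        activation="relu",
        alpha=config.l2_regularization,
        solver="lbfgs",
        max_iter=config.max_iterations,
        tol=config.tol,
        random_state=config.seed,
    )


def _prepare_features(
    X: np.ndarray, config: WNNConfig
) -> tuple[np.ndarray, StandardScaler | None, _pca.PCAModel | None]:
    if not np.all(np.isfinite(X)):
        raise ValueError("training spectra contain non-finite values")
    pca_model = None
    if config.use_pca:
        pca_model = _pca.fit_pca(X)
        pca_model.n_selected = _pca.select_components(pca_model, config.pca_threshold_pct)
        X = _pca.project(X, pca_model)
    scaler = None
    if config.standardize_inputs:
        scaler = StandardScaler().fit(X)
        X = scaler.transform(X)
    return X, scaler, pca_model


def train(library: SpectralLibrary, config: WNNConfig = WNNConfig()) -> WNNModel:
    """Fit the network on the full library; deterministic for a given seed."""
    X, y = library.to_arrays()
    classes = sorted(set(y))
    if len(classes) < 2:
        raise ValueError("training requires at least 2 classes")
    Xt, scaler, pca_model = _prepare_features(X, config)
    net = _make_net(config)
    net.fit(Xt, y)
    cv_acc = None
    counts = library.class_counts()
    if min(counts.values()) >= config.cv_folds:
        cv_acc = cross_validate(library, config)
    return WNNModel(
        net, scaler, pca_model, list(net.classes_), config, cv_acc, library.grid.centers
    )


def cross_validate(library: SpectralLibrary, config: WNNConfig = WNNConfig()) -> float:
    """Mean held-out accuracy (%) over stratified, seeded folds.

    The input transform (PCA, standardization) is refit inside each training
    fold so the estimate is honest.
    """
    X, y = library.to_arrays()
    counts = library.class_counts()
    small = {k: v for k, v in counts.items() if v < config.cv_folds}
    if small:
        raise ValueError(f"classes smaller than the fold count: {small}")
    skf = StratifiedKFold(n_splits=config.cv_folds, shuffle=True, random_state=config.seed)
    accs = []
    for train_idx, test_idx in skf.split(X, y):
        Xt, scaler, pca_model = _prepare_features(X[train_idx], config)
        net = _make_net(config)
        net.fit(Xt, y[train_idx])
        Xv = X[test_idx]
        if pca_model is not None:
            Xv = _pca.project(Xv, pca_model)
        if scaler is not None:
            Xv = scaler.transform(Xv)
        accs.append(float(np.mean(net.predict(Xv) == y[test_idx])))
    return 100.0 * float(np.mean(accs))


def predict_cube(
    refl: ReflectanceCube, model: WNNModel, return_scores: bool = False
) -> PredictionMap:
    """Assign a class to every valid pixel of a calibrated cube."""
    if model.grid_centers is not None and not np.array_equal(
        refl.grid.centers, model.grid_centers
    ):
        raise ValueError("cube wavelength grid does not match the training grid")
    rows, cols, _ = refl.shape
    pixel_ok = refl.valid_pixels()
    flat = refl.data.reshape(rows * cols, -1)
    ok = pixel_ok.ravel()
    labels = np.zeros(rows * cols, dtype=np.int64)
    scores = None
    legend = {0: "invalid"}
    legend.update({i + 1: c for i, c in enumerate(model.classes)})
    if ok.any():
        pred_scores = model.predict_scores(flat[ok])
        pred_idx = pred_scores.argmax(axis=1)
        labels[ok] = pred_idx + 1
        if return_scores:
            scores = np.zeros((rows * cols, len(model.classes)))
            scores[ok] = pred_scores
            scores = scores.reshape(rows, cols, -1)
    lmap = LabelMap(labels.reshape(rows, cols), legend)
    return PredictionMap(lmap, scores)
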