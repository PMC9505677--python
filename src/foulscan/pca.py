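"""Standardized principal component analysis of spectral libraries.

Spectra are standardized (per-channel mean removed, unit variance) with the
training library's statistics, then decomposed; new cubes are projected with
the stored mean/scale and loadings, never re-standardized.  Components are
selected by a cumulative explained-variance threshold (99.99% by default,
which on real 63-channel fouling libraries keeps far fewer components than
channels).  A deterministic sign convention — the largest-magnitude entry
of each loading column is made positive — keeps biplots reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.stats import chi2

__all__ = [
    "PCAModel",
    "EllipseParams",
    "fit_pca",
    "select_components",
    "project",
    "confidence_ellipse",
]


@dataclass
class PCAModel:
    mean: np.ndarray  # per-channel training mean
    scale: np.ndarray  # per-channel training std (1 where variance was 0)
    loadings: np.ndarray  # channels x components, orthonormal columns
    explained_variance_pct: np.ndarray  # descending, sums to 100
    n_selected: int
    zero_variance_channels: np.ndarray = None  # boolean flags

    def __post_init__(self):
        if self.zero_variance_channels is None:
            self.zero_variance_channels = np.zeros(self.mean.shape[0], dtype=bool)

    @property
    def n_channels(self) -> int:
        return self.mean.shape[0]

    def save(self, path: str | Path) -> None:
        np.savez(
            path,
            mean=self.mean,
            scale=self.scale,
            loadings=self.loadings,
            explained_variance_pct=self.explained_variance_pct,
            n_selected=self.n_selected,
            zero_variance_channels=self.zero_variance_channels,
        )

    @classmethod
    def load(cls, path: str | Path) -> "PCAModel":
        with np.load(path) as z:
            return cls(
                z["mean"],
                z["scale"],
                z["loadings"],
                z["explained_variance_pct"],
                int(z["n_selected"]),
                z["zero_variance_channels"],
            )


@dataclass(frozen=True)
class EllipseParams:
    """Confidence ellipse of one class in a 2-D score plane."""

    center: tuple[float, float]
    semi_axes: tuple[float, float]
    angle_rad: float
    level: float
    degenerate: bool = False


def fit_pca(spectra: np.ndarray) -> PCAModel:
    """Fit on an n_samples x n_channels matrix of finite spectra.

    The decomposition is an SVD of the standardized data; explained-variance
    percentages are computed from the singular values and always sum to 100.
    Channels with zero variance get unit scale and contribute nothing.
    """
    X = np.asarray(spectra, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need a 2-D matrix with at least 2 samples")
    if not np.all(np.isfinite(X)):
        raise ValueError("spectra contain non-finite entries")
    mean = X.mean(axis=0)
    std = X.std(axis=0, ddof=1)
    zero_var = std == 0
    scale = np.where(zero_var, 1.0, std)
    Z = (X - mean) / scale
    # economy SVD; columns of V are the loadings
    _, s, vt = np.linalg.svd(Z, full_matrices=False)
    var = s**2
    total = var.sum()
    if total == 0:
        raise ValueError("data has zero total variance")
    explained = 100.0 * var / total
    loadings = vt.T
    # sign convention: largest-magnitude entry of each column positive
    flip = np.sign(loadings[np.abs(loadings).argmax(axis=0), np.arange(loadings.shape[1])])
    flip[flip == 0] = 1.0
    loadings = loadings * flip[None, :]
    return PCAModel(mean, scale, loadings, explained, loadings.shape[1], zero_var)


def select_components(model: PCAModel, threshold_pct: float = 99.99) -> int:
    """Smallest number of leading components whose cumulative explained
    variance reaches the threshold."""
    if not (0.0 < threshold_pct <= 100.0):
        raise ValueError("threshold must be in (0, 100]")
    cum = np.cumsum(model.explained_variance_pct)
    n = int(np.searchsorted(cum, threshold_pct - 1e-9) + 1)
    return min(n, model.loadings.shape[1])


def project(spectra: np.ndarray, model: PCAModel, n_components: int | None = None) -> np.ndarray:
    """Standardize with the TRAINING mean/scale and project onto the leading
    components (``model.n_selected`` by default)."""
    X = np.atleast_2d(np.asarray(spectra, dtype=float))
    if X.shape[1] != model.n_channels:
        raise ValueError(
            f"spectra have {X.shape[1]} channels, model expects {model.n_channels}"
        )
    n = model.n_selected if n_components is None else n_components
    Z = (X - model.mean) / model.scale
    return Z @ model.loadings[:, :n]


def reconstruct(scores: np.ndarray, model: PCAModel) -> np.ndarray:
    """Inverse of :func:`project` (exact when all components are kept)."""
    scores = np.atleast_2d(scores)
    Z = scores @ model.loadings[:, : scores.shape[1]].T
    return Z * model.scale + model.mean


def confidence_ellipse(
    scores_2d: np.ndarray, labels: np.ndarray, level: float = 0.95
) -> dict[str, EllipseParams]:
    """Per-class confidence ellipses in a 2-D score plane.

    Under a Gaussian model, the squared Mahalanobis radius enclosing the
    requested probability mass is the chi-square quantile with 2 degrees of
    freedom; semi-axes are sqrt(quantile * eigenvalue) of the class
    covariance.  Classes with degenerate covariance are flagged.
    """
    scores_2d = np.asarray(scores_2d, dtype=float)
    labels = np.asarray(labels)
    if scores_2d.ndim != 2 or scores_2d.shape[1] != 2:
        raise ValueError("scores must be n x 2")
    if not (0.0 <= level < 1.0):
        raise ValueError("level must be in [0, 1)")
    r2 = chi2.ppf(level, df=2) if level > 0 else 0.0
    out: dict[str, EllipseParams] = {}
    for cls in np.unique(labels):
        pts = scores_2d[labels == cls]
        if pts.shape[0] < 3:
            raise ValueError(f"class {cls} has fewer than 3 points")
        center = pts.mean(axis=0)
        cov = np.cov(pts.T)
        evals, evecs = np.linalg.eigh(cov)
        degenerate = bool(np.min(evals) <= 1e-12 * max(np.max(evals), 1.0))
        evals = np.clip(evals, 0.0, None)
        # eigh returns ascending order; major axis last
        semi = np.sqrt(r2 * evals[::-1])
        major = evecs[:, -1]
        out[str(cls)] = EllipseParams(
            (float(center[0]), float(center[1])),
            (float(semi[0]), float(semi[1])),
            float(np.arctan2(major[1], major[0])),
            level,
            degenerate,
        )
    return out
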