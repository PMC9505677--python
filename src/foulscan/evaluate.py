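"""Confusion-matrix metrics and per-class coverage quantification.

Segmentation quality is measured against a ground-truth label raster with a
confusion matrix (rows = truth, columns = prediction) and derived per-class
rates: TPR (recall) as diagonal over row sum, PPV (precision) as diagonal
over column sum, with FNR = 100 - TPR and FDR = 100 - PPV so the pair
identities hold exactly.  Overall accuracy is the trace over the total.
Coverage is the fraction of valid pixels assigned to each class — the
quantity a coating engineer reads off a fouled test panel.  Invalid or
unlabeled pixels are excluded from every denominator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .classify import PredictionMap
from .hsio import LabelMap

__all__ = ["ConfusionMatrix", "ClassMetrics", "CoverageReport", "confusion", "class_metrics", "coverage"]


@dataclass
class ConfusionMatrix:
    counts: np.ndarray  # K x K integer, rows = truth, cols = prediction
    classes: list[str]
    n_invalid: int = 0

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        k = len(self.classes)
        if self.counts.shape != (k, k):
            raise ValueError("matrix shape must match the class list")
        if np.any(self.counts < 0):
            raise ValueError("counts must be nonnegative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass
class ClassMetrics:
    """Per-class rates in percent; None where the rate is undefined
    (class absent from truth or from predictions)."""

    classes: list[str]
    tpr: dict[str, float | None]
    fnr: dict[str, float | None]
    ppv: dict[str, float | None]
    fdr: dict[str, float | None]
    overall_accuracy: float


@dataclass
class CoverageReport:
    classes: list[str]
    pixel_count: dict[str, int]
    coverage_pct: dict[str, float]
    total_valid: int
    masks: dict[str, np.ndarray]

    def as_text(self) -> str:
        lines = [f"{'class':<16}{'pixels':>10}{'coverage %':>12}"]
        for cls in self.classes:
            lines.append(f"{cls:<16}{self.pixel_count[cls]:>10}{self.coverage_pct[cls]:>12.2f}")
        lines.append(f"{'total valid':<16}{self.total_valid:>10}{100.0:>12.2f}")
        return "\n".join(lines)


def confusion(truth: LabelMap, pred: PredictionMap) -> ConfusionMatrix:
    """Count pixels per (truth, prediction) class pair.

    Pixels invalid in either raster are excluded and tallied separately.
    Both rasters must be defined over one shared class list (the union of
    their legends, ordered by name).
    """
    pred_map = pred.label_map
    if truth.shape != pred_map.shape:
        raise ValueError(f"shape mismatch: truth {truth.shape}, prediction {pred_map.shape}")
    classes = sorted(set(truth.class_names()) | set(pred_map.class_names()))
    index = {name: i for i, name in enumerate(classes)}
    k = len(classes)

    t_lut = _code_to_index(truth, index)
    p_lut = _code_to_index(pred_map, index)
    t_idx = t_lut[truth.labels]
    p_idx = p_lut[pred_map.labels]
    valid = (t_idx >= 0) & (p_idx >= 0)
    n_invalid = int((~valid).sum())
    counts = np.bincount(t_idx[valid] * k + p_idx[valid], minlength=k * k).reshape(k, k)
    return ConfusionMatrix(counts, classes, n_invalid)


def _code_to_index(lmap: LabelMap, index: dict[str, int]) -> np.ndarray:
    lut = np.full(max(lmap.legend) + 1, -1, dtype=np.int64)
    for code, name in lmap.legend.items():
        if code != 0 and name in index:
            lut[code] = index[name]
    return lut


def class_metrics(cm: ConfusionMatrix) -> ClassMetrics:
    """Derive TPR/FNR/PPV/FDR per class and the overall accuracy."""
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    counts = cm.counts.astype(np.int64)
    diag = np.diag(counts)
    row = counts.sum(axis=1)
    col = counts.sum(axis=0)
    tpr, fnr, ppv, fdr = {}, {}, {}, {}
    for i, cls in enumerate(cm.classes):
        if row[i] > 0:
            tpr[cls] = 100.0 * diag[i] / row[i]
            fnr[cls] = 100.0 - tpr[cls]
        else:
            tpr[cls] = fnr[cls] = None
        if col[i] > 0:
            ppv[cls] = 100.0 * diag[i] / col[i]
            fdr[cls] = 100.0 - ppv[cls]
        else:
            ppv[cls] = fdr[cls] = None
    overall = 100.0 * diag.sum() / cm.total
    return ClassMetrics(list(cm.classes), tpr, fnr, ppv, fdr, overall)


def coverage(pred: PredictionMap) -> CoverageReport:
    """Coverage percentage per class over the valid pixels, plus binary
    per-class masks for map rendering."""
    lmap = pred.label_map
    labels = lmap.labels
    valid = labels != 0
    total = int(valid.sum())
    if total == 0:
        raise ValueError("all pixels invalid; coverage undefined")
    classes = lmap.class_names()
    pixel_count, coverage_pct, masks = {}, {}, {}
    for name in classes:
        code = lmap.code_of(name)
        mask = labels == code
        pixel_count[name] = int(mask.sum())
        coverage_pct[name] = 100.0 * pixel_count[name] / total
        masks[name] = mask
    return CoverageReport(classes, pixel_count, coverage_pct, total, masks)
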