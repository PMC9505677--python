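"""Spectral libraries: annotated per-pixel reflectance samples.

A library collects labeled pixel spectra extracted from calibrated cubes
through rectangular ROIs, keeps provenance (cube id, pixel coordinates, ROI
index) so train/test splits can be made spatially disjoint, and supports
coarse (color-group) and fine (species-level) class schemes linked by a
mapping table.  Serialization is a plain CSV: one row per sample with one
reflectance column per channel plus label and provenance columns — diffable
and language-neutral.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .calibrate import ReflectanceCube
from .hsio import ROISet, WavelengthGrid

__all__ = [
    "SpectralSample",
    "SpectralLibrary",
    "ClassSummary",
    "annotate",
    "regroup",
    "summarize",
    "split_spatially_disjoint",
    "COARSE_MAPPING",
]

#: Default fine -> coarse mapping: algae species to color groups, panel
#: colors merged under a single Panel class, animals kept separate.
COARSE_MAPPING = {
    "Ulva": "green_algae",
    "Zostera": "green_algae",
    "Ceramium": "red_algae",
    "Petalonia": "brown_algae",
    "Scytosiphon": "brown_algae",
    "Desmarestia": "brown_algae",
    "Chorda": "brown_algae",
    "mussel": "mussel",
    "barnacle": "barnacle",
    "panel_white": "Panel",
    "panel_gray": "Panel",
    "panel_red": "Panel",
    "panel_blue": "Panel",
}


@dataclass(frozen=True)
class SpectralSample:
    spectrum: np.ndarray
    label: str
    cube_id: str = ""
    row: int = -1
    col: int = -1
    roi_id: int = -1

    def __post_init__(self):
        if not self.label:
            raise ValueError("sample label must be non-empty")


@dataclass
class SpectralLibrary:
    """Labeled spectra sharing one wavelength grid."""

    samples: list[SpectralSample]
    grid: WavelengthGrid
    scheme: str = "fine"

    def __post_init__(self):
        n = len(self.grid)
        for s in self.samples:
            if s.spectrum.shape != (n,):
                raise ValueError("sample spectrum length must match the grid")

    def __len__(self) -> int:
        return len(self.samples)

    @property
    def classes(self) -> list[str]:
        return sorted({s.label for s in self.samples})

    def class_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for s in self.samples:
            counts[s.label] = counts.get(s.label, 0) + 1
        return counts

    def to_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        """(n_samples x n_channels spectra, labels) for model fitting."""
        X = np.stack([s.spectrum for s in self.samples])
        y = np.array([s.label for s in self.samples])
        return X, y

    def cap_per_class(self, cap: int, seed: int | None = None) -> "SpectralLibrary":
        """Seeded per-class subsample of at most *cap* samples (for
        exploratory plots; model fitting uses the full library)."""
        rng = np.random.default_rng(seed)
        by_class: dict[str, list[int]] = {}
        for i, s in enumerate(self.samples):
            by_class.setdefault(s.label, []).append(i)
        keep: list[int] = []
        for label in sorted(by_class):
            idx = by_class[label]
            if len(idx) > cap:
                idx = list(rng.choice(idx, size=cap, replace=False))
            keep.extend(idx)
        keep.sort()
        return SpectralLibrary([self.samples[i] for i in keep], self.grid, self.scheme)

    def to_csv(self, path: str | Path) -> None:
        X, y = self.to_arrays()
        cols = [f"r{w:.0f}" for w in self.grid.centers]
        df = pd.DataFrame(X, columns=cols)
        df["label"] = y
        df["cube_id"] = [s.cube_id for s in self.samples]
        df["row"] = [s.row for s in self.samples]
        df["col"] = [s.col for s in self.samples]
        df["roi_id"] = [s.roi_id for s in self.samples]
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, grid: WavelengthGrid, scheme: str = "fine"):
        df = pd.read_csv(path)
        spec_cols = [c for c in df.columns if c.startswith("r") and c[1:].isdigit()]
        if len(spec_cols) != len(grid):
            raise ValueError(
                f"CSV has {len(spec_cols)} spectral columns, grid has {len(grid)}"
            )
        samples = [
            SpectralSample(
                row[spec_cols].to_numpy(dtype=float),
                str(row["label"]),
                str(row.get("cube_id", "")),
                int(row.get("row", -1)),
                int(row.get("col", -1)),
                int(row.get("roi_id", -1)),
            )
            for _, row in df.iterrows()
        ]
        return cls(samples, grid, scheme)


@dataclass
class ClassSummary:
    """Per-class mean and standard-deviation spectra with sample counts."""

    classes: list[str]
    mean: dict[str, np.ndarray]
    std: dict[str, np.ndarray]
    count: dict[str, int]

    @property
    def total(self) -> int:
        return sum(self.count.values())


def annotate(
    refl: ReflectanceCube, roiset: ROISet, cube_id: str = ""
) -> tuple[list[SpectralSample], int]:
    """Extract one labeled sample per valid pixel of each ROI (row-major).

    Pixels with any invalid channel are skipped; the skip count is returned
    alongside the samples.
    """
    if refl.cube.kind != "reflectance":
        raise ValueError("library annotation requires a calibrated cube")
    roiset.validate_bounds(refl.shape[:2])
    pixel_ok = refl.valid_pixels()
    samples: list[SpectralSample] = []
    skipped = 0
    for roi_id, roi in enumerate(roiset):
        cid = roi.cube_id or cube_id
        for r in range(roi.r0, roi.r1):
            for c in range(roi.c0, roi.c1):
                if pixel_ok[r, c]:
                    samples.append(
                        SpectralSample(refl.data[r, c].copy(), roi.label, cid, r, c, roi_id)
                    )
                else:
                    skipped += 1
    return samples, skipped


def regroup(library: SpectralLibrary, mapping: dict[str, str]) -> SpectralLibrary:
    """Relabel every sample through a fine -> coarse mapping table.

    Sample count and spectra are preserved exactly; only labels change.
    """
    missing = {s.label for s in library.samples} - set(mapping)
    if missing:
        raise KeyError(f"labels not covered by mapping: {sorted(missing)}")
    relabeled = [
        SpectralSample(s.spectrum, mapping[s.label], s.cube_id, s.row, s.col, s.roi_id)
        for s in library.samples
    ]
    return SpectralLibrary(relabeled, library.grid, scheme="coarse")


def summarize(library: SpectralLibrary) -> ClassSummary:
    """Per-class mean and standard-deviation signature across samples."""
    if not library.samples:
        raise ValueError("empty library")
    X, y = library.to_arrays()
    classes = library.classes
    mean, std, count = {}, {}, {}
    for cls in classes:
        sel = X[y == cls]
        if sel.shape[0] == 0:
            raise ValueError(f"class {cls} has no samples")
        mean[cls] = sel.mean(axis=0)
        std[cls] = sel.std(axis=0)
        count[cls] = int(sel.shape[0])
    return ClassSummary(classes, mean, std, count)


def rois_from_labels(
    lmap, per_class: int = 40, size: int = 3, seed: int | None = None, cube_id: str = ""
) -> ROISet:
    """Sample square ROIs fully inside each labeled class region.

    Emulates manual ROI selection on a measured target: for every class a
    set of ``size x size`` squares is drawn at random positions whose full
    extent lies within the class, so no ROI straddles a boundary.
    """
    from scipy.ndimage import binary_erosion

    from .hsio import ROI

    rng = np.random.default_rng(seed)
    rois: list = []
    struct = np.ones((size, size), dtype=bool)
    for code in sorted(lmap.legend):
        if code == 0:
            continue
        name = lmap.legend[code]
        mask = lmap.labels == code
        if not mask.any():
            continue
        # centers whose size x size neighborhood stays inside the class
        interior = binary_erosion(mask, structure=struct, border_value=0)
        centers = np.argwhere(interior)
        if centers.shape[0] == 0:
            continue
        pick = rng.choice(centers.shape[0], size=min(per_class, centers.shape[0]), replace=False)
        half = size // 2
        for idx in pick:
            r, c = centers[idx]
            rois.append(ROI(name, int(r - half), int(r - half + size), int(c - half), int(c - half + size), cube_id))
    return ROISet(rois)


def split_spatially_disjoint(
    library: SpectralLibrary, train_cubes: set[str], test_cubes: set[str]
) -> tuple[SpectralLibrary, SpectralLibrary]:
    """Partition by source cube so no cube contributes to both sides.

    Spatially disjoint train/test cubes avoid leakage through correlated
    neighboring pixels.
    """
    train_cubes, test_cubes = set(train_cubes), set(test_cubes)
    overlap = train_cubes & test_cubes
    if overlap:
        raise ValueError(f"cube ids in both partitions: {sorted(overlap)}")
    train = [s for s in library.samples if s.cube_id in train_cubes]
    test = [s for s in library.samples if s.cube_id in test_cubes]
    return (
        SpectralLibrary(train, library.grid, library.scheme),
        SpectralLibrary(test, library.grid, library.scheme),
    )
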