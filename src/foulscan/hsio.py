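"""Hypercube, label-raster and ROI input/output.

Hypercubes are stored on disk in the ENVI convention: a small text header
(``.hdr``) describing dimensions, data type, interleave and the wavelength
list, next to a raw binary payload.  Band-sequential (BSQ) is the native
layout; BIL/BIP payloads are converted to BSQ on read.  Label rasters are
single-band ENVI byte images with a sidecar text legend.  ROI sets are plain
text, one rectangle per line.

Coordinates are 0-based and row-major; rectangles are half-open
``[r0, r1) x [c0, c1)`` so that area arithmetic is unambiguous.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "WavelengthGrid",
    "Hypercube",
    "LabelMap",
    "ROI",
    "ROISet",
    "build_wavelength_grid",
    "read_hypercube",
    "write_hypercube",
    "read_label_map",
    "write_label_map",
    "read_roiset",
    "write_roiset",
    "extract_roi_pixels",
]

#: Reserved label-raster code for invalid / unlabeled pixels.
INVALID_CODE = 0
INVALID_NAME = "invalid"

_ENVI_DTYPES = {
    1: np.dtype("uint8"),
    2: np.dtype("int16"),
    3: np.dtype("int32"),
    4: np.dtype("float32"),
    5: np.dtype("float64"),
    12: np.dtype("uint16"),
    13: np.dtype("uint32"),
}
_ENVI_CODES = {v: k for k, v in _ENVI_DTYPES.items()}


@dataclass(frozen=True)
class WavelengthGrid:
    """Uniform grid of channel center wavelengths in nanometres."""

    start_nm: float
    stop_nm: float
    step_nm: float

    @property
    def centers(self) -> np.ndarray:
        n = len(self)
        return self.start_nm + self.step_nm * np.arange(n)

    def __len__(self) -> int:
        return int(np.floor((self.stop_nm - self.start_nm) / self.step_nm)) + 1

    def __eq__(self, other) -> bool:
        if not isinstance(other, WavelengthGrid):
            return NotImplemented
        return (
            self.start_nm == other.start_nm
            and self.step_nm == other.step_nm
            and len(self) == len(other)
        )

    def __hash__(self) -> int:
        return hash((self.start_nm, self.step_nm, len(self)))

    def index_of(self, wavelength_nm: float) -> int:
        """Channel index of the center closest to *wavelength_nm*."""
        return int(np.argmin(np.abs(self.centers - wavelength_nm)))


def build_wavelength_grid(start_nm: float, stop_nm: float, step_nm: float) -> WavelengthGrid:
    """Build the channel grid for a wavelength scan.

    The number of channels is ``floor((stop - start) / step) + 1``: a scan of
    420–730 nm in 5 nm steps gives 63 channels.
    """
    if step_nm <= 0:
        raise ValueError(f"step must be positive, got {step_nm}")
    if stop_nm < start_nm:
        raise ValueError(f"stop ({stop_nm}) must be >= start ({start_nm})")
    return WavelengthGrid(float(start_nm), float(stop_nm), float(step_nm))


@dataclass
class Hypercube:
    """A rows x cols x channels stack of raw counts or reflectance.

    ``kind`` is either ``"raw_counts"`` or ``"reflectance"``.  Reflectance may
    slightly exceed 1 (chlorophyll autofluorescence shows up as apparent
    reflectance above the standard's level near 720 nm).  NaN is only allowed
    where a validity mask marks pixels invalid.
    """

    data: np.ndarray
    grid: WavelengthGrid
    kind: str = "raw_counts"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"cube must be 3-D, got shape {self.data.shape}")
        if self.data.shape[2] != len(self.grid):
            raise ValueError(
                f"cube has {self.data.shape[2]} channels but grid has {len(self.grid)}"
            )
        if self.kind not in ("raw_counts", "reflectance"):
            raise ValueError(f"unknown cube kind {self.kind!r}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def n_channels(self) -> int:
        return self.data.shape[2]


@dataclass
class LabelMap:
    """Integer class raster with a code -> name legend.

    Code 0 is reserved for invalid/unlabeled pixels and is always present in
    the legend.
    """

    labels: np.ndarray
    legend: dict[int, str]

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise ValueError("label raster must be 2-D")
        self.legend = {int(k): str(v) for k, v in self.legend.items()}
        self.legend.setdefault(INVALID_CODE, INVALID_NAME)
        present = set(np.unique(self.labels).tolist())
        missing = present - set(self.legend)
        if missing:
            raise ValueError(f"raster codes {sorted(missing)} missing from legend")

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape

    def class_names(self) -> list[str]:
        """Legend names excluding the invalid code, ordered by code."""
        return [self.legend[c] for c in sorted(self.legend) if c != INVALID_CODE]

    def code_of(self, name: str) -> int:
        for code, n in self.legend.items():
            if n == name:
                return code
        raise KeyError(name)


@dataclass(frozen=True)
class ROI:
    """Half-open rectangle ``[r0, r1) x [c0, c1)`` with a class label."""

    label: str
    r0: int
    r1: int
    c0: int
    c1: int
    cube_id: str = ""

    @property
    def area(self) -> int:
        return max(0, self.r1 - self.r0) * max(0, self.c1 - self.c0)


@dataclass
class ROISet:
    rois: list[ROI]

    def __post_init__(self) -> None:
        if not self.rois:
            raise ValueError("ROI set must be non-empty")

    def __iter__(self):
        return iter(self.rois)

    def __len__(self) -> int:
        return len(self.rois)

    def validate_bounds(self, shape: tuple[int, int]) -> None:
        rows, cols = shape
        for roi in self.rois:
            if not (0 <= roi.r0 < roi.r1 <= rows and 0 <= roi.c0 < roi.c1 <= cols):
                raise ValueError(f"ROI {roi} out of bounds for {rows}x{cols} image")


# ---------------------------------------------------------------------------
# ENVI header + raw binary


def _write_envi_header(path: Path, shape, dtype, interleave, wavelengths=None, extra=None):
    rows, cols, bands = shape
    lines = [
        "ENVI",
        f"samples = {cols}",
        f"lines = {rows}",
        f"bands = {bands}",
        "header offset = 0",
        "file type = ENVI Standard",
        f"data type = {_ENVI_CODES[np.dtype(dtype)]}",
        f"interleave = {interleave}",
        "byte order = 0",
    ]
    if wavelengths is not None:
        lines.append("wavelength units = nm")
        wl = ", ".join(f"{w:.6g}" for w in wavelengths)
        lines.append("wavelength = { " + wl + " }")
    for key, value in (extra or {}).items():
        lines.append(f"{key} = {value}")
    path.write_text("\n".join(lines) + "\n")


def _parse_envi_header(path: Path) -> dict:
    text = path.read_text()
    if not text.lstrip().startswith("ENVI"):
        raise ValueError(f"{path} is not an ENVI header")
    # fold { ... } blocks onto one line before parsing key = value pairs
    text = re.sub(r"\{[^}]*\}", lambda m: m.group(0).replace("\n", " "), text)
    header: dict = {}
    for line in text.splitlines():
        if "=" not in line:
            continue
        key, _, value = line.partition("=")
        header[key.strip().lower()] = value.strip()
    return header


def write_hypercube(cube: Hypercube, path: str | Path) -> None:
    """Write a cube as ENVI header + band-sequential binary.

    *path* is the binary payload path; the header is written next to it with
    a ``.hdr`` suffix appended.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    data = np.ascontiguousarray(np.moveaxis(cube.data, 2, 0))  # BSQ: band, row, col
    extra = {"cube kind": cube.kind}
    for key, value in cube.metadata.items():
        extra[f"meta {key}"] = value
    _write_envi_header(
        path.with_suffix(path.suffix + ".hdr"),
        cube.shape,
        data.dtype,
        "bsq",
        wavelengths=cube.grid.centers,
        extra=extra,
    )
    data.tofile(path)


def read_hypercube(path: str | Path) -> Hypercube:
    """Read an ENVI cube written by :func:`write_hypercube` (or compatible)."""
    path = Path(path)
    header = _parse_envi_header(path.with_suffix(path.suffix + ".hdr"))
    rows = int(header["lines"])
    cols = int(header["samples"])
    bands = int(header["bands"])
    dtype = _ENVI_DTYPES[int(header["data type"])]
    interleave = header.get("interleave", "bsq").lower()
    if "wavelength" not in header:
        raise ValueError(f"{path}: header has no wavelength list")
    wl = np.array(
        [float(v) for v in header["wavelength"].strip("{} ").split(",") if v.strip()]
    )
    if wl.size != bands:
        raise ValueError(f"{path}: {wl.size} wavelengths for {bands} bands")

    payload = np.fromfile(path, dtype=dtype)
    if payload.size != rows * cols * bands:
        raise ValueError(
            f"{path}: payload has {payload.size} values, header declares {rows * cols * bands}"
        )
    if interleave == "bsq":
        data = payload.reshape(bands, rows, cols)
        data = np.moveaxis(data, 0, 2)
    elif interleave == "bil":
        data = payload.reshape(rows, bands, cols)
        data = np.moveaxis(data, 1, 2)
    elif interleave == "bip":
        data = payload.reshape(rows, cols, bands)
    else:
        raise ValueError(f"unknown interleave {interleave!r}")

    step = float(wl[1] - wl[0]) if bands > 1 else 1.0
    grid = WavelengthGrid(float(wl[0]), float(wl[-1]), step)
    if len(grid) != bands or not np.allclose(grid.centers, wl):
        raise ValueError(f"{path}: wavelength list is not a uniform grid")
    kind = header.get("cube kind", "raw_counts")
    metadata = {
        key[len("meta "):]: value for key, value in header.items() if key.startswith("meta ")
    }
    return Hypercube(np.ascontiguousarray(data), grid, kind=kind, metadata=metadata)


def write_label_map(lmap: LabelMap, path: str | Path) -> None:
    """Write the raster as a single-band ENVI byte image plus ``.legend`` text."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    raster = lmap.labels.astype(np.uint8)
    if not np.array_equal(raster, lmap.labels):
        raise ValueError("label codes must fit in a byte raster")
    _write_envi_header(
        path.with_suffix(path.suffix + ".hdr"), (*lmap.shape, 1), raster.dtype, "bsq"
    )
    raster.tofile(path)
    legend_lines = [f"{code}\t{name}" for code, name in sorted(lmap.legend.items())]
    path.with_suffix(path.suffix + ".legend").write_text("\n".join(legend_lines) + "\n")


def read_label_map(path: str | Path) -> LabelMap:
    path = Path(path)
    header = _parse_envi_header(path.with_suffix(path.suffix + ".hdr"))
    rows, cols = int(header["lines"]), int(header["samples"])
    raster = np.fromfile(path, dtype=_ENVI_DTYPES[int(header["data type"])])
    if raster.size != rows * cols:
        raise ValueError(f"{path}: payload size does not match header")
    legend = {}
    for line in path.with_suffix(path.suffix + ".legend").read_text().splitlines():
        if line.strip():
            code, _, name = line.partition("\t")
            legend[int(code)] = name.strip()
    return LabelMap(raster.reshape(rows, cols).astype(np.int64), legend)


def write_roiset(roiset: ROISet, path: str | Path) -> None:
    """One record per line: ``label r0 r1 c0 c1 [cube_id]``, whitespace-separated."""
    lines = ["# label r0 r1 c0 c1 cube_id"]
    for roi in roiset:
        lines.append(f"{roi.label} {roi.r0} {roi.r1} {roi.c0} {roi.c1} {roi.cube_id}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_roiset(path: str | Path) -> ROISet:
    rois = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) < 5:
            raise ValueError(f"bad ROI record: {line!r}")
        label, r0, r1, c0, c1 = parts[:5]
        cube_id = parts[5] if len(parts) > 5 else ""
        rois.append(ROI(label, int(r0), int(r1), int(c0), int(c1), cube_id))
    return ROISet(rois)


def extract_roi_pixels(cube: Hypercube, roi: ROI) -> list[tuple[tuple[int, int], np.ndarray]]:
    """All pixel spectra inside *roi*, row-major, as ((row, col), spectrum) pairs."""
    rows, cols, _ = cube.shape
    if not (0 <= roi.r0 < roi.r1 <= rows and 0 <= roi.c0 < roi.c1 <= cols):
        raise ValueError(f"ROI {roi} out of bounds for {rows}x{cols} cube")
    out = []
    for r in range(roi.r0, roi.r1):
        for c in range(roi.c0, roi.c1):
            out.append(((r, c), cube.data[r, c, :]))
    return out
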