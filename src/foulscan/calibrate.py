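"""Two-point pixel-wise reflectance calibration and spectral smoothing.

Three raw hypercubes acquired under one exposure plan — the scene I, a
bright field I_ref of a uniform diffuse standard (reflectance R_ref, 10% by
default), and a dark field I_d — determine the reflectance at every pixel
and channel independently:

    R(x, y, l) = R_ref(l) * (I - I_d) / (I_ref - I_d)

Because the transform is a per-pixel ratio, every multiplicative spatial
term of the acquisition (illumination profile, filter aperture transmission,
vignetting) cancels: this is the flat-field property.  Entries where the
bright field carries no usable signal (denominator below a guard) or where
the scene/bright cubes saturated are flagged invalid rather than producing
spurious reflectance; negative numerators are clipped to zero and noted in
the mask.

Spectra are then low-pass filtered along the wavelength axis with a
Savitzky-Golay filter (order 2, window 9 channels = 45 nm at 5 nm sampling
by default), which smooths noise without flattening the broad spectral
features used for classification.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import savgol_filter

from .hsio import Hypercube

__all__ = [
    "CalibrationSet",
    "ReflectanceCube",
    "reflectance_transform",
    "smooth_spectra",
    "make_validity_mask",
    "DEFAULT_DENOM_GUARD",
]

#: Minimum usable bright-minus-dark signal (counts); below it the entry is
#: treated as underexposed and flagged invalid.
DEFAULT_DENOM_GUARD = 10.0


@dataclass
class CalibrationSet:
    """Scene, bright-field and dark-field cubes sharing grid, dims and plan."""

    scene: Hypercube
    bright: Hypercube
    dark: Hypercube
    r_ref: float | np.ndarray = 0.10
    saturation_ceiling: float = 2**14 - 1

    def __post_init__(self) -> None:
        cubes = (self.scene, self.bright, self.dark)
        if any(c.kind != "raw_counts" for c in cubes):
            raise ValueError("calibration requires raw-count cubes")
        shapes = {c.shape for c in cubes}
        if len(shapes) != 1:
            raise ValueError(f"cube dimensions differ: {shapes}")
        if not (self.scene.grid == self.bright.grid == self.dark.grid):
            raise ValueError("cubes are on different wavelength grids")
        r = np.asarray(self.r_ref, dtype=float)
        if r.ndim == 1 and r.shape[0] != self.scene.n_channels:
            raise ValueError("per-wavelength r_ref must have one value per channel")
        if np.any(r <= 0) or np.any(r > 1):
            raise ValueError("r_ref must lie in (0, 1]")

    def r_ref_per_channel(self) -> np.ndarray:
        r = np.asarray(self.r_ref, dtype=float)
        if r.ndim == 0:
            return np.full(self.scene.n_channels, float(r))
        return r


@dataclass
class ReflectanceCube:
    """Calibrated cube plus a per-pixel-channel validity mask.

    Invalid entries keep a placeholder value of 0 but must never be used;
    consumers filter on ``valid``.
    """

    cube: Hypercube
    valid: np.ndarray
    clipped: np.ndarray = None  # entries where a negative numerator was clipped

    def __post_init__(self) -> None:
        if self.cube.kind != "reflectance":
            raise ValueError("ReflectanceCube requires kind='reflectance'")
        if self.valid.shape != self.cube.shape:
            raise ValueError("mask shape must match cube shape")
        if self.clipped is None:
            self.clipped = np.zeros(self.cube.shape, dtype=bool)

    @property
    def data(self) -> np.ndarray:
        return self.cube.data

    @property
    def grid(self):
        return self.cube.grid

    @property
    def shape(self):
        return self.cube.shape

    def valid_pixels(self) -> np.ndarray:
        """Pixels whose full spectrum is valid."""
        return self.valid.all(axis=2)


def make_validity_mask(
    calset: CalibrationSet, denom_guard: float = DEFAULT_DENOM_GUARD
) -> np.ndarray:
    """True where the entry is well exposed in all three cubes.

    Flags saturation in the scene or bright field (counts at or above the
    ADC ceiling) and underexposure (bright minus dark below the guard).
    """
    ceiling = calset.saturation_ceiling
    saturated = (calset.scene.data >= ceiling) | (calset.bright.data >= ceiling)
    denom = calset.bright.data - calset.dark.data
    underexposed = denom <= denom_guard
    return ~(saturated | underexposed)


def reflectance_transform(
    calset: CalibrationSet, denom_guard: float = DEFAULT_DENOM_GUARD
) -> ReflectanceCube:
    """Apply the two-point transform pixel-wise and channel-wise."""
    valid = make_validity_mask(calset, denom_guard)
    numer = calset.scene.data - calset.dark.data
    denom = calset.bright.data - calset.dark.data
    clipped = (numer < 0) & valid
    numer = np.clip(numer, 0.0, None)
    r_ref = calset.r_ref_per_channel()[None, None, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        refl = r_ref * numer / denom
    refl = np.where(valid, refl, 0.0)
    cube = Hypercube(
        refl,
        calset.scene.grid,
        kind="reflectance",
        metadata={**calset.scene.metadata, "calibrated": "two-point"},
    )
    return ReflectanceCube(cube, valid, clipped)


def smooth_spectra(
    refl: ReflectanceCube, poly_order: int = 2, window_channels: int = 9
) -> ReflectanceCube:
    """Savitzky-Golay filter each pixel spectrum along the wavelength axis.

    Spatial dimensions are untouched.  Edge channels are handled by fitting
    the polynomial within the first/last window and evaluating it at the
    edge (scipy's ``interp`` mode).  Pixels containing any invalid channel
    are left unfiltered and keep their invalid flags: the filter must not
    smear placeholder values into valid channels.
    """
    if window_channels % 2 == 0:
        raise ValueError("window must be odd")
    if window_channels <= poly_order:
        raise ValueError("window must exceed the polynomial order")
    if window_channels > refl.cube.n_channels:
        raise ValueError("window larger than the number of channels")
    out = refl.data.copy()
    full = refl.valid.all(axis=2)
    smoothed = savgol_filter(
        refl.data, window_channels, poly_order, axis=2, mode="interp"
    )
    out[full] = smoothed[full]
    cube = Hypercube(
        out,
        refl.grid,
        kind="reflectance",
        metadata={
            **refl.cube.metadata,
            "smoothing": f"savitzky-golay order={poly_order} window={window_channels}",
            "sg_edges": "polynomial fit within first/last window",
        },
    )
    return ReflectanceCube(cube, refl.valid.copy(), refl.clipped.copy())
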