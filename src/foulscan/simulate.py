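"""Radiometric forward model of an LCTF staring hyperspectral imager.

Simulates the full acquisition chain of a liquid-crystal-tunable-filter
(LCTF) camera imaging fouled test panels through water: per channel the
recorded counts are

    I(x, y, lambda) = t_exp * [ I_d(x, y)
        + G * sum_l' I_s(x, y, l') * exp(-2 a(l') d_w) * R(x, y, l')
              * tau_TF(l', lambda) * tau_O(l') * Resp(l') * dl' ]

with t_exp the per-channel exposure, I_d the dark-current rate, G the
electron-multiplication gain, I_s the source spectral radiance (separable
spatial x spectral), a the attenuation coefficient of water over a two-way
path 2*d_w, R the surface reflectance, tau_TF the LCTF passband at center
wavelength lambda, tau_O the lens transmission and Resp the sensor
responsivity.  Exposure multiplies both the dark and signal terms: both
accumulate over the integration time.  All spectral curves live on a fine
1 nm internal grid and the integral is a trapezoid-rule quadrature.

The scene generator builds panel targets carrying patches of biofouling
(green/red/brown algae, mussels, barnacles) whose endmember spectra encode
the diagnostic features of these organisms: chlorophyll-a absorption dips
near 450 and 665 nm, a red-algae satellite dip near 615 nm, color-driven
reflectance peaks (green 545 nm, brown 570 nm, red 590+640 nm) and an
apparent-reflectance peak near 720 nm where chl-a autofluorescence outshines
elastic scattering.  The 720 nm feature is emulated as reflectance because
that is how a reflectance-calibrated imager records it.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .hsio import Hypercube, LabelMap, WavelengthGrid, build_wavelength_grid

__all__ = [
    "FINE_GRID_NM",
    "LCTFModel",
    "WaterModel",
    "InstrumentModel",
    "EndmemberSpectrum",
    "SceneMap",
    "ExposurePlan",
    "ShapeSpec",
    "default_instrument",
    "default_endmember_params",
    "lctf_passband",
    "generate_endmember",
    "generate_scene",
    "plan_exposures",
    "simulate_raw_cube",
    "COARSE_CLASSES",
    "FINE_SPECIES",
]

#: Internal fine wavelength grid (nm) for all spectral curves and quadrature.
FINE_GRID_NM = np.arange(400.0, 750.0 + 1e-9, 1.0)
_FINE_STEP = 1.0

COARSE_CLASSES = ["panel_white", "green_algae", "red_algae", "brown_algae", "mussel", "barnacle"]

#: Species-level grouping: each species inherits its color group's endmember
#: parameters and differs only through seeded jitter.
FINE_SPECIES = {
    "Ulva": "green_algae",
    "Zostera": "green_algae",
    "Ceramium": "red_algae",
    "Petalonia": "brown_algae",
    "Scytosiphon": "brown_algae",
    "Desmarestia": "brown_algae",
    "Chorda": "brown_algae",
}


def _gauss(x: np.ndarray, center: float, fwhm: float) -> np.ndarray:
    sigma = fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    return np.exp(-0.5 * ((x - center) / sigma) ** 2)


# ---------------------------------------------------------------------------
# Instrument components


@dataclass(frozen=True)
class LCTFModel:
    """Liquid crystal tunable filter: FWHM and peak transmission grow
    monotonically with center wavelength; both are interpolated linearly
    between the endpoint values over the tuning range."""

    range_nm: tuple[float, float] = (420.0, 730.0)
    fwhm_endpoints_nm: tuple[float, float] = (6.8, 14.4)
    peak_transmission_endpoints: tuple[float, float] = (0.0072, 0.236)

    def fwhm(self, cwl: float) -> float:
        lo, hi = self.range_nm
        f0, f1 = self.fwhm_endpoints_nm
        return float(np.interp(cwl, [lo, hi], [f0, f1]))

    def peak_transmission(self, cwl: float) -> float:
        lo, hi = self.range_nm
        t0, t1 = self.peak_transmission_endpoints
        return float(np.interp(cwl, [lo, hi], [t0, t1]))


@dataclass(frozen=True)
class WaterModel:
    """Two-way extinction in the water column.

    The default attenuation curve is a smooth monotone pure-water-like
    shape: low and flat through the blue-green, rising steeply toward
    730 nm.  ``path_length_m = 0`` disables water extinction.
    """

    path_length_m: float = 0.35
    refractive_index: float = 1.33
    attenuation_table: tuple[tuple[float, float], ...] | None = None

    def attenuation(self, wavelengths_nm: np.ndarray) -> np.ndarray:
        """Attenuation coefficient (1/m) at the requested wavelengths."""
        wl = np.asarray(wavelengths_nm, dtype=float)
        if self.attenuation_table is not None:
            tab = np.asarray(self.attenuation_table, dtype=float)
            return np.interp(wl, tab[:, 0], tab[:, 1])
        # smooth exponential rise toward the red, ~0.05/m at 420, ~2.5/m at 730
        return 0.04 + 0.012 * np.exp((wl - 420.0) / 58.0)


def _default_led_spectrum(wl: np.ndarray) -> np.ndarray:
    """Phosphor-converted white LED: narrow blue pump + broad phosphor band."""
    return 0.9 * _gauss(wl, 452.0, 22.0) + 1.0 * _gauss(wl, 575.0, 140.0)


def _default_responsivity(wl: np.ndarray) -> np.ndarray:
    """Silicon EMCCD responsivity: broad peak near 600 nm, falling in the red."""
    return 0.35 + 0.65 * _gauss(wl, 590.0, 260.0)


@dataclass(frozen=True)
class InstrumentModel:
    """All terms of the forward model, with wavelength-dependent curves
    sampled on :data:`FINE_GRID_NM`.

    ``illumination_profile(rows, cols)`` returns the spatial part of I_s:
    by default an inverse-square horizontal falloff (the source sits to the
    right of the frame, tilted ~15 deg, so intensity decreases toward the
    left) times a uniform vertical profile.
    """

    lctf: LCTFModel = field(default_factory=LCTFModel)
    water: WaterModel = field(default_factory=WaterModel)
    led_radiance_scale: float = 4.0e5
    dark_current_rate: float = 200.0  # counts/s, spatially uniform
    em_gain: float = 20.0
    well_depth_e: float = 26000.0
    adc_bits: int = 14
    read_noise_counts: float = 2.0
    illum_tilt_strength: float = 0.35  # fractional left-right falloff

    @property
    def saturation_ceiling(self) -> float:
        return float(2**self.adc_bits - 1)

    @property
    def electrons_per_count(self) -> float:
        return self.well_depth_e / 2**self.adc_bits

    def led_spectrum(self, wl: np.ndarray) -> np.ndarray:
        return self.led_radiance_scale * _default_led_spectrum(wl)

    def optics_transmission(self, wl: np.ndarray) -> np.ndarray:
        return np.full_like(np.asarray(wl, dtype=float), 0.9)

    def responsivity(self, wl: np.ndarray) -> np.ndarray:
        return _default_responsivity(wl)

    def illumination_profile(self, rows: int, cols: int) -> np.ndarray:
        # inverse-square falloff with distance to a source right of the frame
        x = np.arange(cols, dtype=float)
        if cols > 1:
            x = x / (cols - 1)  # 0 (left, far) .. 1 (right, near)
        d = 1.0 + self.illum_tilt_strength * (1.0 - x)
        horiz = 1.0 / d**2
        return np.tile(horiz, (rows, 1))


def default_instrument(**overrides) -> InstrumentModel:
    return replace(InstrumentModel(), **overrides) if overrides else InstrumentModel()


def lctf_passband(lctf: LCTFModel, cwl: float) -> np.ndarray:
    """LCTF transmission curve at center wavelength *cwl* on the fine grid.

    Gaussian with the interpolated FWHM, truncated at +/-3 sigma, scaled to
    the interpolated peak transmission.
    """
    lo, hi = lctf.range_nm
    if not (lo <= cwl <= hi):
        raise ValueError(f"CWL {cwl} nm outside filter range [{lo}, {hi}]")
    fwhm = lctf.fwhm(cwl)
    sigma = fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    band = lctf.peak_transmission(cwl) * _gauss(FINE_GRID_NM, cwl, fwhm)
    band[np.abs(FINE_GRID_NM - cwl) > 3.0 * sigma] = 0.0
    return band


# ---------------------------------------------------------------------------
# Endmembers and scenes


@dataclass(frozen=True)
class EndmemberSpectrum:
    """Reflectance curve of one class on the fine grid."""

    name: str
    reflectance: np.ndarray  # on FINE_GRID_NM, >= 0
    brightness_jitter: float = 0.10  # per-pixel lognormal sigma

    def __post_init__(self):
        if np.any(self.reflectance < 0) or not np.all(np.isfinite(self.reflectance)):
            raise ValueError("endmember reflectance must be finite and nonnegative")


def default_endmember_params() -> dict[str, dict]:
    """Feature parameterization per class.

    Curves are built as ``(baseline + tilt + peaks) * prod(1 - dip)``: peaks
    are additive Gaussians ``(center, fwhm, amplitude)``, dips multiplicative
    Gaussians ``(center, fwhm, depth)`` with depth < 1 so reflectance stays
    nonnegative.  Levels: white panel ~45%, mussels ~4%, algae below 16%
    outside the 720 nm autofluorescence peak.
    """
    chla = [(450.0, 30.0, 0.50), (665.0, 35.0, 0.55)]
    return {
        "panel_white": dict(baseline=0.45, tilt=0.0, peaks=[], dips=[]),
        "panel_gray": dict(baseline=0.24, tilt=0.0, peaks=[], dips=[]),
        "panel_red": dict(baseline=0.08, tilt=0.0, peaks=[(645.0, 60.0, 0.22)], dips=[]),
        "panel_blue": dict(baseline=0.08, tilt=0.0, peaks=[(455.0, 50.0, 0.18)], dips=[]),
        "green_algae": dict(
            baseline=0.070,
            tilt=0.0,
            peaks=[(545.0, 60.0, 0.065), (720.0, 26.0, 0.11)],
            dips=list(chla),
        ),
        "brown_algae": dict(
            baseline=0.055,
            tilt=0.0,
            peaks=[(570.0, 70.0, 0.038), (720.0, 26.0, 0.085)],
            dips=[(450.0, 30.0, 0.45), (665.0, 35.0, 0.50)],
        ),
        "red_algae": dict(
            baseline=0.050,
            tilt=0.0,
            peaks=[(590.0, 34.0, 0.055), (640.0, 30.0, 0.055), (720.0, 26.0, 0.15)],
            dips=list(chla) + [(615.0, 26.0, 0.25)],
        ),
        "mussel": dict(baseline=0.035, tilt=0.015, peaks=[], dips=[]),
        "barnacle": dict(
            baseline=0.20,
            tilt=0.0,
            peaks=[(720.0, 26.0, 0.03)],
            dips=[(665.0, 35.0, 0.12)],
        ),
    }


def generate_endmember(
    class_name: str,
    seed: int | None = None,
    params: dict | None = None,
    brightness_jitter: float = 0.10,
    dip_depth_jitter: float = 0.10,
) -> EndmemberSpectrum:
    """Build one class endmember, deterministically for a given seed.

    ``dip_depth_jitter`` perturbs dip depths (fractional, lognormal) so that
    replicate endmembers — e.g. algae species within one color group — share
    features but are not identical.  Species names from the fine grouping
    resolve to their color group's parameters.
    """
    all_params = default_endmember_params()
    base_name = FINE_SPECIES.get(class_name, class_name)
    if params is None:
        if base_name not in all_params:
            raise ValueError(f"unknown endmember class {class_name!r}")
        params = all_params[base_name]
    rng = np.random.default_rng(seed)
    wl = FINE_GRID_NM
    curve = np.full_like(wl, params["baseline"], dtype=float) + params.get("tilt", 0.0) * (
        (wl - wl[0]) / (wl[-1] - wl[0])
    )
    for center, fwhm, amp in params.get("peaks", []):
        curve = curve + amp * _gauss(wl, center, fwhm)
    for center, fwhm, depth in params.get("dips", []):
        d = depth * rng.lognormal(0.0, dip_depth_jitter) if dip_depth_jitter > 0 else depth
        d = min(d, 0.95)
        curve = curve * (1.0 - d * _gauss(wl, center, fwhm))
    return EndmemberSpectrum(class_name, np.clip(curve, 0.0, None), brightness_jitter)


@dataclass(frozen=True)
class ShapeSpec:
    """One patch in a scene layout: a rectangle, ellipse or random blob."""

    kind: str  # rectangle | ellipse | blob
    label: str
    center: tuple[float, float]  # (row, col)
    size: tuple[float, float]  # rectangle: (height, width); ellipse/blob: semi-axes

    def rasterize(self, rows: int, cols: int, rng: np.random.Generator) -> np.ndarray:
        rr, cc = np.mgrid[0:rows, 0:cols]
        r0, c0 = self.center
        a, b = self.size
        if self.kind == "rectangle":
            return (
                (rr >= r0 - a / 2) & (rr < r0 + a / 2) & (cc >= c0 - b / 2) & (cc < c0 + b / 2)
            )
        if self.kind == "ellipse":
            return ((rr - r0) / a) ** 2 + ((cc - c0) / b) ** 2 <= 1.0
        if self.kind == "blob":
            # ellipse with a lumpy angular radius modulation
            theta = np.arctan2(rr - r0, cc - c0)
            n_lobes = int(rng.integers(3, 7))
            phase = rng.uniform(0, 2 * np.pi)
            mod = 1.0 + 0.25 * np.cos(n_lobes * theta + phase)
            return ((rr - r0) / a) ** 2 + ((cc - c0) / b) ** 2 <= mod**2
        raise ValueError(f"unknown shape kind {self.kind!r}")


@dataclass
class SceneMap:
    """Ground truth for a simulated target: label raster, per-class
    endmembers, and a per-pixel brightness field.

    The realized per-pixel reflectance is
    ``R*(x, y, l') = brightness(x, y) * endmember[label(x, y)](l')``.
    """

    label_map: LabelMap
    endmembers: dict[str, EndmemberSpectrum]
    brightness: np.ndarray

    @property
    def shape(self) -> tuple[int, int]:
        return self.label_map.shape

    def class_reflectance_matrix(self) -> tuple[np.ndarray, np.ndarray]:
        """(codes, K x n_fine matrix) of endmember curves ordered by label code."""
        codes = sorted(c for c in self.label_map.legend if c != 0)
        mat = np.stack([self.endmembers[self.label_map.legend[c]].reflectance for c in codes])
        return np.asarray(codes), mat

    def realized_reflectance(self) -> np.ndarray:
        """Full rows x cols x n_fine reflectance cube R* (can be large)."""
        codes, mat = self.class_reflectance_matrix()
        lut = np.zeros((int(codes.max()) + 1, mat.shape[1]))
        lut[codes] = mat
        return self.brightness[:, :, None] * lut[self.label_map.labels]

    def true_coverage(self) -> dict[str, float]:
        """Ground-truth coverage percentages from the label raster."""
        labels = self.label_map.labels
        valid = labels != 0
        total = int(valid.sum())
        out = {}
        for code, name in sorted(self.label_map.legend.items()):
            if code == 0:
                continue
            out[name] = 100.0 * int((labels == code).sum()) / total
        return out


def generate_scene(
    layout: list[ShapeSpec],
    endmembers: dict[str, EndmemberSpectrum],
    shape: tuple[int, int],
    background: str = "panel_white",
    seed: int | None = None,
    brightness_jitter: float | None = None,
) -> SceneMap:
    """Rasterize a layout of fouling patches onto a panel background.

    Overlapping shapes are resolved by draw order (later wins).  Each pixel
    gets a multiplicative brightness drawn lognormally with its class's
    jitter sigma (or a global override); jitter 0 gives brightness 1
    everywhere.
    """
    rows, cols = shape
    if background not in endmembers:
        raise ValueError(f"background class {background!r} has no endmember")
    rng = np.random.default_rng(seed)
    class_names = [background] + [
        s.label for s in layout if s.label != background and s.label in endmembers
    ]
    # preserve first-appearance order, unique
    seen: dict[str, int] = {}
    for name in class_names:
        if name not in seen:
            seen[name] = len(seen) + 1
    for s in layout:
        if s.label not in endmembers:
            raise ValueError(f"shape label {s.label!r} has no endmember")
    labels = np.full(shape, seen[background], dtype=np.int64)
    for s in layout:
        mask = s.rasterize(rows, cols, rng)
        labels[mask] = seen[s.label]
    legend = {0: "invalid"}
    legend.update({code: name for name, code in seen.items()})
    lmap = LabelMap(labels, legend)

    brightness = np.ones(shape, dtype=float)
    for name, code in seen.items():
        sigma = brightness_jitter if brightness_jitter is not None else endmembers[name].brightness_jitter
        if sigma > 0:
            mask = labels == code
            brightness[mask] = rng.lognormal(0.0, sigma, size=int(mask.sum()))
    return SceneMap(lmap, dict(endmembers), brightness)


# ---------------------------------------------------------------------------
# Exposure planning and acquisition


@dataclass(frozen=True)
class ExposurePlan:
    """Per-channel exposure times in seconds."""

    grid: WavelengthGrid
    t_exp_s: np.ndarray

    def __post_init__(self):
        t = np.asarray(self.t_exp_s, dtype=float)
        if t.shape != (len(self.grid),):
            raise ValueError("one exposure per channel required")
        if not np.all(np.isfinite(t)) or np.any(t <= 0):
            raise ValueError("exposures must be positive and finite")
        object.__setattr__(self, "t_exp_s", t)


def _channel_weights(instrument: InstrumentModel, grid: WavelengthGrid) -> np.ndarray:
    """n_channels x n_fine quadrature weights W such that the noise-free
    signal rate per pixel is ``G * profile * (W @ R*)`` counts/s."""
    wl = FINE_GRID_NM
    common = (
        instrument.led_spectrum(wl)
        * np.exp(-2.0 * instrument.water.attenuation(wl) * instrument.water.path_length_m)
        * instrument.optics_transmission(wl)
        * instrument.responsivity(wl)
    )
    bands = np.stack([lctf_passband(instrument.lctf, cwl) for cwl in grid.centers])
    # trapezoid rule on the uniform fine grid
    w = np.full(wl.shape, _FINE_STEP)
    w[0] = w[-1] = _FINE_STEP / 2.0
    return bands * common[None, :] * w[None, :]


def plan_exposures(
    instrument: InstrumentModel,
    grid: WavelengthGrid,
    reference_reflectance: float = 0.10,
    target_fill: float = 0.8,
) -> ExposurePlan:
    """Choose per-channel exposures so the brightest pixel of a uniform
    reference surface reaches ``target_fill`` of the saturation ceiling.

    Mirrors per-channel exposure adjustment on the real instrument: low LCTF
    transmission and LED output in the blue, and water absorption plus
    falling responsivity in the red, force long exposures at the spectral
    extremes relative to mid-band channels.
    """
    if not (0.0 < target_fill < 1.0):
        raise ValueError("target_fill must be in (0, 1)")
    weights = _channel_weights(instrument, grid)
    rate = instrument.em_gain * reference_reflectance * weights.sum(axis=1)
    if np.any(rate <= 0):
        bad = grid.centers[rate <= 0]
        raise ValueError(f"zero expected signal at channels {bad}; cannot expose")
    # brightest pixel of the spatial profile sets the headroom
    peak_profile = 1.0  # profile maximum is 1 by construction
    t = target_fill * instrument.saturation_ceiling / (rate * peak_profile)
    return ExposurePlan(grid, t)


def simulate_raw_cube(
    scene: SceneMap,
    instrument: InstrumentModel,
    plan: ExposurePlan,
    mode: str = "scene",
    ref_reflectance: float = 0.10,
    noise: bool = True,
    seed: int | None = None,
) -> Hypercube:
    """Acquire one raw-count hypercube of the scene, a dark field, or a
    uniform reference (bright field).

    Noise, when enabled, combines Poisson shot noise with an EM excess-noise
    factor of sqrt(2), Poisson dark current and Gaussian read noise; all
    draws come from one generator seeded by *seed*.  Counts are clipped to
    [0, 2^adc_bits - 1].
    """
    if mode not in ("scene", "dark", "reference"):
        raise ValueError(f"unknown mode {mode!r}")
    rows, cols = scene.shape
    grid = plan.grid
    n_ch = len(grid)
    t = plan.t_exp_s

    dark_mean = t[None, None, :] * instrument.dark_current_rate  # counts

    if mode == "dark":
        signal_rate = np.zeros((rows, cols, n_ch))
    else:
        weights = _channel_weights(instrument, grid)  # (C, F)
        profile = instrument.illumination_profile(rows, cols)
        if mode == "reference":
            per_class_signal = ref_reflectance * weights.sum(axis=1)  # (C,)
            signal_rate = instrument.em_gain * profile[:, :, None] * per_class_signal[None, None, :]
        else:
            codes, mat = scene.class_reflectance_matrix()
            class_signal = mat @ weights.T  # (K, C)
            lut = np.zeros((int(codes.max()) + 1, n_ch))
            lut[codes] = class_signal
            signal_rate = (
                instrument.em_gain
                * profile[:, :, None]
                * scene.brightness[:, :, None]
                * lut[scene.label_map.labels]
            )

    mean_counts = dark_mean + t[None, None, :] * signal_rate

    if noise:
        rng = np.random.default_rng(seed)
        k = instrument.electrons_per_count
        dark_e = dark_mean * k
        signal_e = (t[None, None, :] * signal_rate) * k
        noisy_dark_e = rng.poisson(dark_e).astype(float)
        # shot noise with EM excess factor sqrt(2): Poisson plus an extra
        # Gaussian term doubles the variance to 2 * signal_e
        noisy_signal_e = rng.poisson(signal_e).astype(float) + rng.normal(
            0.0, np.sqrt(signal_e)
        )
        counts = (noisy_dark_e + noisy_signal_e) / k + rng.normal(
            0.0, instrument.read_noise_counts, size=mean_counts.shape
        )
    else:
        counts = mean_counts

    counts = np.clip(counts, 0.0, instrument.saturation_ceiling)
    meta = {"mode": mode, "noise": str(noise), "seed": str(seed)}
    return Hypercube(counts, grid, kind="raw_counts", metadata=meta)


def demo_layout(shape: tuple[int, int] = (120, 160)) -> list[ShapeSpec]:
    """A six-class model-target layout: algae patches, a mussel cluster and
    barnacles on a white panel."""
    rows, cols = shape
    r, c = rows / 120.0, cols / 160.0
    return [
        ShapeSpec("ellipse", "green_algae", (30 * r, 40 * c), (18 * r, 24 * c)),
        ShapeSpec("rectangle", "red_algae", (32 * r, 110 * c), (34 * r, 40 * c)),
        ShapeSpec("blob", "brown_algae", (85 * r, 45 * c), (22 * r, 28 * c)),
        ShapeSpec("ellipse", "mussel", (88 * r, 115 * c), (16 * r, 20 * c)),
        ShapeSpec("ellipse", "barnacle", (60 * r, 80 * c), (8 * r, 10 * c)),
    ]
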