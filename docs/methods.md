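# Methods

## Forward instrument model

The simulator reproduces the acquisition chain of a staring LCTF
hyperspectral imager viewing a submerged panel: for each channel (center
wavelength λ, scanned 420–730 nm in 5 nm steps, 63 channels) the recorded
counts are the exposure-scaled sum of dark current and the spectrally
integrated signal

I(x,y,λ) = t_exp(λ)·[I_d + G·Σ_λ′ I_s(x,y,λ′)·e^(−2α(λ′)d_w)·R(x,y,λ′)·τ_TF(λ′,λ)·τ_O(λ′)·ℜ(λ′)·Δλ′].

Exposure multiplies both the dark and the signal terms — both accumulate
over the integration time. All spectral curves live on a common internal
1 nm grid over 400–750 nm and the integral is a trapezoid-rule quadrature
on that grid. The geometric mapping between panel and image coordinates is
the identity: refraction at the air–water interface only rescales the field
of view, which is irrelevant to per-pixel spectral classification.

Model assumptions: parameters constant over one exposure; no extinction in
air; homogeneous water absorption over a fixed two-way path 2·d_w
(default d_w = 0.35 m, settable to 0); Lambertian surfaces; separable
illumination (spatial profile × LED spectrum).

### Component defaults

| parameter | default | why |
|---|---|---|
| LCTF FWHM | 6.8 → 14.4 nm, linear in CWL | published endpoint values; the interpolation law between them is not published, linear is the simplest monotone choice |
| LCTF peak transmission | 0.72% → 23.6%, linear in CWL | same |
| passband shape | Gaussian at the stated FWHM, truncated at ±3σ | only the FWHM is known; a smooth symmetric unimodal kernel is the neutral choice |
| EM gain G | 20 | operating point of the real camera |
| well depth / ADC | 26 000 e⁻ / 14 bit (ceiling 16 383) | real sensor format |
| dark current | 200 counts/s, uniform | cooled-sensor order of magnitude; exact value cancels in calibration |
| read noise | 2 counts RMS | small relative to shot noise, typical for this class of sensor |
| LED spectrum | blue pump (452 nm) + broad phosphor band (~575 nm) | shape of a phosphor-converted white LED covering the full filter range |
| responsivity | broad silicon curve peaking near 590 nm | qualitative silicon EMCCD response |
| water attenuation α(λ) | 0.04 + 0.012·exp((λ−420)/58) m⁻¹ | smooth pure-water-like monotone rise toward the red (~0.05/m blue, ~2.5/m at 730 nm); user-overridable as a table |
| illumination profile | inverse-square horizontal falloff (~35% left-to-right), uniform vertically | the light source sits beside the camera, tilted ~15°, so intensity drops toward the far edge of the frame |

### Noise model

The original acquisition software is a black box, so the noise model is the
package's own: Poisson shot noise on the signal expressed in well electrons
(counts × 26 000/2¹⁴ ≈ 1.59 e⁻/count) with an EM excess-noise factor √2
(implemented as an added Gaussian term that doubles the shot variance),
Poisson dark current, and Gaussian read noise, all drawn from one seeded
generator. Counts are clipped to [0, 2¹⁴−1]; `noise=False` gives the exact
deterministic forward model for algebraic tests. Under this model SNR grows
as √t_exp, which the planner and tests rely on.

### Exposure planning

Each channel's exposure is chosen so that the brightest pixel of a uniform
reference surface (by default the brightest endmember, the white panel at
~45% reflectance, with a ×1.35 jitter margin) reaches 80% of the ADC
ceiling. Because blue channels suffer low LCTF transmission and LED output,
and red channels water absorption and falling responsivity, the planned
exposures are largest at the spectral extremes — the same qualitative
pattern the real instrument needs (hundreds of ms at 430 and 730 nm versus
a few ms mid-band).

### Endmembers

Class spectra are built on the fine grid as
(baseline + tilt + Σ additive Gaussian peaks) × Π(1 − depth·Gaussian dip),
which keeps reflectance nonnegative for dip depths < 1. The parameter sets
encode the reported signatures: all algae carry chlorophyll-a absorption
dips at 450 and 665 nm and an apparent-reflectance peak at 720 nm
(autofluorescence recorded as reflectance by a reflectance-calibrated
imager — the forward model has no emission term, so the peak is emulated in
the endmember, and calibrated values may slightly exceed the standard's
level there); green algae peak at 545 nm, brown at 570 nm (flatter,
darker), red at 590 and 640 nm with a satellite dip at 615 nm; algae stay
below 16% reflectance outside the fluorescence peak; the white panel is
flat near 45%, mussels near 4% with a slight red tilt, barnacles ~20% with
a weak chl-a imprint. Replicate endmembers (e.g. algae species within one
color group) share these parameters and differ only through seeded jitter
of the dip depths (lognormal, σ = 0.10); within a scene each pixel
additionally gets a lognormal brightness factor (σ = 0.10) emulating
orientation, density and health variation.

What the generator does **not** emulate: mixed boundary pixels
(every pixel is a pure class), spatial texture within an organism beyond
scalar brightness, bidirectional reflectance effects, water turbidity or
background light. Passing tests therefore demonstrate the correctness of
the pipeline's algebra and the achievability of the classification task
under pigment-driven spectral separations, not field performance on real
panels.

## Calibration

R = R_ref·(I − I_d)/(I_ref − I_d) per pixel and channel, with R_ref = 0.10
(a 10% diffuse standard maximizes dynamic range given the dark fouling
classes). Guards: entries with bright-minus-dark below 10 counts
(configurable) or with saturated scene/bright counts are flagged invalid,
never silently zeroed; negative numerators (noise below dark level) are
clipped to 0 and annotated. Because the transform is a per-pixel ratio of
cubes sharing one exposure plan, it is exactly invariant to any positive
spatial illumination field and to per-channel exposure rescaling — both
properties are tested to machine precision.

Spectra are then smoothed along wavelength with a second-order
Savitzky–Golay filter over 9 channels (45 nm). Edge channels use the
polynomial fitted within the first/last window (recorded in the output
metadata); pixels containing invalid channels are left unfiltered so
placeholder values never leak into valid neighbors. The processing order is
calibrate → smooth → annotate/classify.

For spectrally flat surfaces the two-point recovery is exact; for curved
spectra the finite LCTF passband biases the estimate by an amount growing
with curvature × FWHM², which is inherent to the instrument (deconvolution
of the instrument response is out of scope).

## Library, PCA, classifier

Libraries hold one row per annotated pixel (63 reflectance values + label +
provenance: cube id, pixel, ROI). Train/test splits are made by source cube
so test pixels are never spatial neighbors of training pixels. Class
imbalance is kept as collected (no rebalancing), matching practice; a
seeded per-class cap exists for exploratory plots only.

PCA standardizes with the training mean/scale (zero-variance channels get
unit scale and are flagged), decomposes by SVD, fixes signs so each loading
column's largest-magnitude entry is positive, and keeps the smallest number
of components reaching 99.99% cumulative variance (15–18 of 63 on default
synthetic libraries). New cubes reuse the stored transform.

The classifier is a single-hidden-layer network of 100 ReLU units with no
L2 penalty on standardized (PCA-projected) inputs. The original training
toolbox's optimizer and schedule are unrecoverable, so training uses L-BFGS
with seeded initialization, up to 400 iterations, tolerance 1e-6 —
standard for shallow networks of this size and deterministic given the
seed. Accuracy is estimated by stratified five-fold cross-validation with
the input transform refit inside each fold. Prediction is a per-pixel
softmax argmax (ties break to the lowest class index); masked pixels get a
reserved invalid code and are excluded from confusion and coverage
denominators.

## Pipeline and problem sizes

`run_pipeline` derives per-stage seeds from one global seed via
`SeedSequence.spawn`, simulates a training target (one stripe per class)
and a spatially disjoint test target (scattered ellipses/blobs/rectangles),
acquires scene/bright/dark triples for each, calibrates, smooths, samples
40 ROIs of 3×3 pixels per class from the training ground truth, trains,
classifies the test cube and reports confusion, rates and coverage, with a
config-hash provenance record in every output directory. Test-target
endmembers are re-realized with a fresh seed by default, emulating
different physical specimens of the same classes.

Default frames are 120×160 (demo) and 96×128 (acceptance experiments) —
large enough for thousands of test pixels per class while keeping a full
coarse+fine experiment under half a minute. The scaled-down coarse/fine
experiment reproduces the qualitative finding that color-group
classification is highly accurate (≥ 90%, typically ~99% here) while
species-level classification of spectrally near-identical species drops to
roughly 80–87%.

## Known limitations

- No spectral deconvolution of the LCTF response; narrow features are
  blurred by design.
- No mixed-pixel handling: boundary pixels get a single label, the main
  error source on real targets.
- The 720 nm chlorophyll feature is modeled as reflectance, not
  irradiance-dependent fluorescence.
- The ENVI reader supports BSQ natively and converts BIL/BIP on read; no
  georeferencing, no compressed payloads.
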