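# foulscan

Hyperspectral quantification of marine biofouling on coated test panels.

Fouling-control coatings are evaluated by submerging coated panels at sea
and scoring how much of the surface is colonized by algae, mussels and
barnacles. `foulscan` implements the full analysis chain of a staring-type
hyperspectral imager built around a liquid crystal tunable filter (LCTF)
that scans 420–730 nm in 5 nm steps (63 channels): pixel-wise reflectance
calibration, spectral-library construction, PCA dimensionality reduction,
per-pixel wide-neural-network classification, and per-class coverage
reporting. Because the measured spectra carry the optical fingerprints of
photosynthetic pigments — chlorophyll-a absorption near 450 and 665 nm and
its autofluorescence near 720 nm — the classifier separates fouling groups
that RGB-based scoring confuses.

The package also contains a radiometric **forward simulator** of the whole
instrument, so every stage is testable without the hardware. Recorded
counts per pixel and channel follow

```
I(x,y,λ) = t_exp(λ) · [ I_d + G · ∫ I_s(x,y,λ′) e^(−2α(λ′)d_w) R(x,y,λ′)
                                   τ_TF(λ′,λ) τ_O(λ′) ℜ(λ′) dλ′ ]
```

with per-channel exposure `t_exp`, dark current `I_d`, EM gain `G`, source
radiance `I_s`, two-way water attenuation `e^(−2αd_w)`, surface reflectance
`R`, LCTF passband `τ_TF`, lens transmission `τ_O` and sensor responsivity
`ℜ`. Reflectance is recovered from three cubes (scene `I`, bright field
`I_ref` of a 10% diffuse standard, dark field `I_d`) by the pixel-wise
two-point transform

```
R(x,y,λ) = R_ref(λ) · (I − I_d) / (I_ref − I_d)
```

which cancels every spatial and spectral term of the instrument and medium
(flat-field property). Segmentation quality is reported as a confusion
matrix with per-class TPR/FNR/PPV/FDR, and coverage as the fraction of
valid pixels per class.

## Worked example

Run the packaged demo: a simulated 120×160×63 panel bearing green/red/brown
algae, a mussel cluster and barnacles, imaged through 35 cm of water with
the default noise model, then calibrated, classified and quantified.

```python
from foulscan.pipeline import run_pipeline

report = run_pipeline({}, seed=1, out_dir="runs/demo")
print(f"overall accuracy: {report['overall_accuracy_pct']:.2f}%")
```

Output:

```
CV accuracy (train library): 99.95%
PCA components kept: 15
overall accuracy: 99.96%
  barnacle       est   3.08%   truth   3.05%
  brown_algae    est   3.23%   truth   3.23%
  green_algae    est   5.21%   truth   5.21%
  mussel         est   2.86%   truth   2.86%
  panel_white    est  78.16%   truth  78.19%
  red_algae      est   7.45%   truth   7.45%
```

The classifier is trained on a spatially disjoint simulated target (a
separate cube), 15 of 63 principal components carry 99.99% of the library
variance, and the estimated coverage of each class tracks the ground-truth
label fractions to within a few hundredths of a percent. Training at the
species level instead of the color-group level (`{"scheme": "fine"}`) drops
accuracy to the low 80s because algae species within one color group share
pigmentation and differ only by small spectral jitter.

The same workflow is available from the shell:

```sh
foulscan simulate --shape 120,160 --out runs/raw
foulscan calibrate --scene runs/raw/scene.raw --bright runs/raw/reference.raw \
                   --dark runs/raw/dark.raw --rref 0.10 --out runs/cal
foulscan run --seed 1 --out runs/full          # full pipeline from defaults
```

Cubes are stored as ENVI-convention text headers plus band-sequential
binary; libraries as plain CSV; ROI sets and legends as line-oriented text.

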