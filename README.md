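# nanosyn

Nanoscale quantification of protein clusters at excitatory synapses from
high- and super-resolution fluorescence microscopy, with a synthetic-data
generator that makes the entire analysis chain verifiable against known
ground truth.

The motivating problem comes from neurodegeneration research: phosphorylated
TDP-43 (pTDP-43) forms diffraction-limited clusters inside spinal-cord
synapses, and the questions — *what fraction of VGLUT1 vs VGLUT2 presynaptic
terminals and PSD95-marked postsynaptic densities contain such clusters, how
large are the clusters, and does a disease model change any of this?* —
are answered by a stack of standard but fiddly image-quantification steps.
`nanosyn` implements that stack as a tested library for microscopists and
image analysts:

- **Scene simulation** (`nanosyn.scene`, `nanosyn.render`): ground-truth
  synapses (terminal + apposed PSD ellipses, physical nm coordinates) with
  per-compartment cluster occupancy, rendered as confocal / Airyscan /
  g-STED / TIRF images (Gaussian PSF, Poisson shot noise) or as DNA-PAINT
  style localization event streams with configurable precision.
- **Spot sizing** (`nanosyn.spots`): the four-line-profile estimator — find
  intensity maxima, draw horizontal/vertical/diagonal profiles, fit each to
  a Gaussian `I(x) = B + A·exp(−(x−μ)²/2σ²)`, report the mean
  `FWHM = 2√(2 ln 2)·σ ≈ 2.3548σ`, and exclude spots with any profile
  `R² < 0.8` or a mean FWHM outside a plausible window.
- **Segmentation & colocalization** (`nanosyn.segment`): rolling-ball
  background subtraction, Gaussian blur, thresholding (fixed or Otsu),
  connected-component particle analysis with size filters; object-based
  colocalization (≥ 1 shared pixel); synapse classification (VGLUT1 synapse
  = VGLUT1 ∩ PSD95 regardless of VGLUT2; VGLUT2 synapse = VGLUT2 ∩ PSD95
  with zero VGLUT1 overlap); centroid-rule cluster-in-structure counting in
  2D or 3D.
- **SMLM pipeline** (`nanosyn.smlm`): per-frame background subtraction, 2D
  Gaussian peak fitting with Thompson-style precision
  `σ_loc = √((s² + a²/12)/N)`, quality filtering (signal ≥ 20, photons ≥ 50,
  precision ≤ 40 nm, all inclusive), DBSCAN clustering (ε = 40 nm,
  minPts = 5), precision-corrected cluster diameters, cluster–terminal
  association, and Fourier ring correlation resolution (odd/even frame
  split, 10 nm rendering pixel, 1/7 threshold).
- **Statistics** (`nanosyn.stats`): Shapiro–Wilk routing, pooled-variance
  two-sample t, exact Mann–Whitney U, one-way ANOVA + Tukey HSD, Type II
  two-way ANOVA, Pearson χ² association without continuity correction,
  control-normalized percentages.
- **Orchestration** (`nanosyn.pipeline`, `nanosyn` CLI): config-driven
  imaging, localization and two-arm comparison studies with per-animal
  aggregation (the animal is the statistical unit).

## Worked example

Sizing the same ~120 nm ground-truth clusters through three modalities
(`python examples/02_spot_sizing.py`):

```
confocal  n=100 accepted  mean 312.3 nm  median 314.6 nm  (convolution law predicts 323.1 nm)
airyscan  n=100 accepted  mean 212.1 nm  median 212.3 nm  (convolution law predicts 216.3 nm)
gsted     n=100 accepted  mean 147.9 nm  median 148.1 nm  (convolution law predicts 150.0 nm)
```

Identical 120 nm objects appear three different sizes because each
modality's PSF adds in quadrature
(`FWHM_obs ≈ √(FWHM_true² + FWHM_psf²)`); the strictly decreasing ordering
is the fingerprint of increasing optical resolution, and the few-percent
gap to the convolution-law prediction is the pixel-sampling and fitting
error of the estimator itself.

Association of clusters with terminal subtypes from pooled counts
(30 VGLUT1 terminals, 80% containing clusters, vs 145 VGLUT2 at 51%):

```python
>>> import nanosyn as ns
>>> r = ns.chi_squared_association([[24, 6], [74, 71]])
>>> round(r.statistic, 2), r.df, round(r.p_value, 4)
(8.46, 1.0, 0.0036)
```

a significant χ²(1) — clusters preferentially occupy VGLUT1 terminals.

Other entry points: `examples/01_generate_scene.py` (ground truth),
`03_synapse_quantification.py` (image pipeline), `04_smlm_pipeline.py`
(localization pipeline), `05_group_comparison.py` (two-arm study), or the
CLI (`nanosyn synth`, `nanosyn segcoloc`, `nanosyn smlm`, `nanosyn stats`,
`nanosyn reproduce-all`).

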