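# Methods

This note records the models, estimators and numerical choices behind
`nanosyn`, and what the synthetic studies do and do not establish.

## Synthetic scenes

A scene is a square field (default 20 µm side) of excitatory synapses in
physical nm coordinates. Synapse counts are Poisson at configurable
densities; the defaults encode the qualitative anatomy of ventral-horn
neuropil: VGLUT1 terminals sparse and large (4 / 100 µm², mean area
0.8 µm²), VGLUT2 terminals four-fold denser and four-fold smaller
(16 / 100 µm², 0.2 µm²). Absolute densities and areas are stand-ins chosen
for realism — the source literature gives only the large/sparse vs
small/abundant contrast — and are fully configurable. Terminals are
ellipses (aspect ratio U(1,2), random orientation); each carries one PSD
ellipse (mean 0.15 µm², elongated, major axis tangential) placed on the
terminal boundary so that roughly a quarter of the PSD lies inside the
terminal (`psd_overlap_frac = 0.25`). Partial overlap is guaranteed by
construction (penetration depth `2·f·r_psd` ≫ one pixel); overlap is what
defines a "synapse" for the downstream classifier.

Cluster placement is the parameter of scientific interest: each of the four
compartment kinds (VGLUT1/VGLUT2 × terminal/PSD) has an independent
Bernoulli occupancy probability, defaulting to 0.876 / 0.596 / 0.462 /
0.457 — the healthy-control containment fractions the analysis should
recover. Occupied compartments hold `1 + Poisson(0.5)` clusters placed
uniformly inside the compartment ellipse, with truncated-normal diameters
(120 ± 25 nm for imaging studies; 55 ± 10 nm for localization studies).
A multiplicative `genotype_effect` (< 1 = disease) scales VGLUT1 terminal
and VGLUT1-associated PSD areas only, modelling a structure-specific
deficit with no cluster effect.

One generator, three observation models:

1. **Intensity images.** Structures are rasterized at the modality's pixel
   size (confocal 85 nm, Airyscan 35 nm, g-STED 20 nm, TIRF 107 nm; the
   TIRF value derives from a 16 µm camera pixel behind 60× · 2.5×
   magnification) as flat ellipses (amplitude 300) or Gaussian spots
   (σ = diameter/2.3548, peak 800), convolved with a Gaussian PSF
   (FWHM 300 / 180 / 90 / 300 nm — plausible effective resolutions, chosen
   so the three modalities preserve their real-world ordering; the source
   never states instrument PSFs), plus constant background (20) and Poisson
   shot noise on signal + background. No read noise, no depletion-beam or
   detector-array optics: the contracts tested downstream depend only on
   the Gaussian-blur + shot-noise structure. Pixel `i` covers
   `[i·p, (i+1)·p)` nm with its center at `(i+0.5)·p`.
2. **Localization event streams.** Per frame, each cluster emits
   Poisson-distributed binding events, positioned uniformly in the cluster
   disc and detected with isotropic Gaussian error (default 20 nm, the
   nominal accuracy of aptamer-PAINT labelling). Photons are log-normal
   (median 600, σ_log 0.5). When a stream is ingested directly as a
   localization table (bypassing the camera), the quality columns are
   derived from the generative model: precision scales as the Thompson
   `1/√N` law anchored at the stream's nominal error, and signal strength
   is a photons-proportional amplitude/noise proxy. The camera path
   (`fit_peaks`) instead computes all three from the actual 2D Gaussian
   fit.
3. **Fixture sets.** TIFF images, ground-truth CSVs and localization CSVs
   plus a JSON manifest with every seed; byte-identical on re-runs.

What the generator does *not* emulate: tissue autofluorescence and
antibody background, object shape irregularity (everything is elliptical or
disc-like), axial structure (scenes are 2D; the 3D code paths are exercised
on stacked masks), emitter blinking kinetics and drift. Passing
recovery tests therefore demonstrates correctness of the measurement chain
under a clean forward model, not robustness to every real-tissue artifact.

## Spot sizing

Maxima detection uses a local-contrast rule: a pixel is a peak if it is the
maximum of its `(2·min_sep+1)²` neighbourhood and exceeds the neighbourhood
minimum by a prominence threshold; surviving peaks closer than `min_sep`
pixels merge to the brighter (ties to lower (row, col)). Profiles are
centred on the integer peak (no sub-pixel re-centring, matching the
plugin-style workflow); diagonal samples are spaced `√2·pixel`. Each of the
four profiles is fit by unweighted least squares to the 4-parameter
Gaussian; fits are validated post hoc (finite σ > 0, positive amplitude,
centre within the profile) rather than bounded during optimisation, which
is ~50× faster and equally robust on these inputs. Acceptance requires all
four `R² ≥ 0.8` and mean FWHM inside [40, 800] nm — both thresholds are
declared defaults (the source workflow states the rules but not the
numbers). Rejection reasons are ordered `fit_failure` > `low_r2` >
`out_of_range`, and peaks within half a line length of the border are
rejected as `out_of_range` without fitting.

## Segmentation and counting

Rolling-ball background subtraction uses the true ball (not a flat disc)
via `skimage.restoration.rolling_ball`; radii above 8 px run on a
block-minimum shrunken image and the background is bilinearly enlarged —
the classic speed-up, accurate to the smoothness of the background. 3D
stacks are processed per plane. Connectivity is 4-connected (2D) /
6-connected (3D). Thresholds are a fixed value or Otsu; binarization is
`I ≥ t`.

Cluster-in-structure counting uses the centroid rule (a cluster belongs to
the structure whose foreground contains its centroid; `overlap` available
as config), which behaves identically in 2D and 3D and keeps counts
conservative (Σ per-structure ≤ total clusters). An exclusive variant
(postsynaptic = in PSD but not in any terminal) was evaluated and rejected:
it strips genuine PSD clusters in the terminal–PSD overlap zone and
deflates postsynaptic containment by ~14 points.

The study pipelines fix the structure-channel thresholds at 140 counts
(cluster channel: Otsu). This stands in for the blinded *manual*
thresholding of the original workflow, whose operational target is that
segmented structures look the right size: 140 makes segmented marker area
track true marker area closely at the default render settings, which keeps
the two occupancy-measurement biases — boundary-zone cross-talk from
dilated masks, and edge-cluster loss from eroded masks — simultaneously
within ~3 percentage points across all four compartment categories. Otsu
remains the library default for unknown data.

## Localization analysis

Filtering is inclusive on all three thresholds (signal ≥ 20, photons ≥ 50,
precision ≤ 40 nm); the inclusivity convention is declared, not sourced.
DBSCAN uses scikit-learn with `eps = 40 nm`, `min_samples = 5` (the point
itself counts, so five mutually-close points are a cluster); an O(n²)
brute-force implementation serves as the test oracle, never the
implementation.

**Cluster diameter.** The default estimator is the precision-corrected RMS
diameter

    d̂ = 2√2 · √( S/(m−1) − 2·mean(σ_loc²) ),

with `S` the summed squared deviation of the `m` member localizations from
their mean. For localizations drawn uniformly from a disc of diameter `d`,
`E[S/(m−1)] = d²/8 + 2σ_loc²`, so `d̂` is unbiased for the disc diameter at
every `m`; in simulation at σ_loc = 20 nm it recovers a 55 nm disc with
median 49–54 nm across m = 5–25. The naive maximum-pairwise-distance
definition is noise-inflated (median 73–123 nm for the same data — the max
of many ~28 nm-scale noisy pairwise distances grows with m) and cannot
recover sub-100 nm structures at DNA-PAINT precision; it remains available
as `method="max_pairwise"`. On noiseless inputs the two agree on the
canonical examples (coincident points → 0; two points 100 nm apart with
midpoints → 100 nm).

**FRC.** Localizations are split by odd/even frame parity, each half
rendered as a 2D histogram at a 10 nm pixel, and the ring-wise correlation
`Σ F₁F₂* / √(Σ|F₁|² Σ|F₂|²)` smoothed (5-ring moving average) and scanned
for its first crossing of the fixed 1/7 threshold; the inverse crossing
frequency is the resolution, with linear interpolation between rings. No
crossing before Nyquist returns an explicit unresolved sentinel (NaN +
flag) — e.g. for duplicated halves. At saturating localization density the
estimate plateaus near 3σ_loc (≈ 57–61 nm at σ = 20 nm), consistent with
the analytic crossing of a Gaussian-blurred spectrum at threshold 1/7
(≈ 2πσ/√(2 ln 7) ≈ 3.2σ); reported resolutions should be read against that
floor. Doubling σ_loc approximately doubles the estimate in the
noise-dominated regime.

## Statistics

The t test is pooled-variance (reported animal-level degrees of freedom
`n₁+n₂−2` match this variant); both-groups-degenerate data use the
convention t = 0, p = 1 (equal means) / p = 0 (unequal). Mann–Whitney U
uses full-enumeration exact p-values when `n₁·n₂ ≤ 400` and there are no
ties, otherwise the tie-corrected normal approximation. One-way ANOVA
reports an infinite-F sentinel when within-group variance vanishes with
unequal means; Tukey HSD comes from the studentized-range distribution.
The two-way ANOVA uses Type II sums of squares (standard for main-effect
inference on the unbalanced 5-vs-6-animal design); the group-comparison
pipeline fits main effects only, which reproduces the animal-level df
structure (F(1,39) for 4 structures × 11 animals; F(1,19) for 2 × 11) of
the study design it emulates, while the interaction is available via
`include_interaction=True`. A constant response yields F = 0 by
convention. χ² is Pearson's without continuity correction (the worked
2×2 example is only reproduced uncorrected); a zero expected count returns
a NaN sentinel with a warning. The Shapiro–Wilk gate delegates W to scipy
and implements only the routing contract (p ≥ 0.05 → parametric; n < 3 →
non-parametric with warning). Control normalization divides by the control
mean (×100); on balanced designs it is a positive rescaling and leaves
ANOVA F statistics exactly unchanged, so the pipeline tests raw values and
normalizes for display only.

## Study orchestration and problem sizes

Per-animal aggregation averages image-level metrics within an animal; the
animal is the unit for between-group tests. Between-animal variability is
a multiplicative log-normal size factor (CV 8%) applied to all structure
area means — enough to dominate within-animal sampling noise at the
default ~100+ synapses per animal, giving the 0.7× VGLUT1 effect an
animal-level effect size ≳ 3 SD (power ≈ 1 at 5 + 6 animals) while null
effects stay at their nominal 5% false-positive rate.

The two-arm comparison defaults to *scene-level* measurement (metrics read
from ground truth per image) so that repeated-run calibration experiments
(hundreds of complete studies) are cheap; `measurement="image"` runs the
full render-and-segment chain per image for end-to-end use. Simulation
sizes throughout (image counts, field sizes, frame counts) were chosen as
the smallest that leave parameter-recovery checks dominated by systematic
rather than sampling error; all are config fields, not constants.

## Known limitations

- Ellipse/disc geometry only; no irregular boutons, no perforated PSDs.
- 2D scenes; 3D segmentation/counting paths are tested on synthetic stacks
  rather than generated volumes.
- No drift, no multi-emitter fitting, no blinking kinetics in the SMLM
  model; FRC is therefore an upper-bound-quality estimate for ideal data.
- Otsu on strongly non-bimodal channels can dilate structures; use fixed
  thresholds (as the study configs do) when object area matters.
- The diameter estimator assumes a uniform-disc emitter distribution and
  trustworthy per-localization precision estimates; ring-like or clumped
  label distributions would bias it.
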