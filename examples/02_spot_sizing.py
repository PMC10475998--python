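"""Measure apparent cluster diameters under three imaging modalities.

Renders the same ~120 nm ground-truth clusters as confocal, Airyscan and
g-STED images and sizes each spot with the four-line-profile Gaussian FWHM
estimator.  The measured mean shrinks as the PSF narrows, following
FWHM_obs ~= sqrt(FWHM_true^2 + FWHM_psf^2).
"""

import math

import nanosyn as ns

scene = ns.make_spot_grid_scene(100, diameter_nm=120.0, diameter_sd_nm=15.0,
                                seed=7)
for modality, line_px in (("confocal", 15), ("airyscan", 21), ("gsted", 25)):
    image = ns.render_channel_image(scene, modality, "pTDP43")
    measurements = ns.measure_spots(image, prominence=50,
                                    line_length_px=line_px)
    s = ns.summarize_diameters(measurements)
    psf = ns.MODALITIES[modality].psf_fwhm_nm
    print(f"{modality:9s} n={s.n:3d} accepted  mean {s.mean_nm:5.1f} nm  "
          f"median {s.median_nm:5.1f} nm  "
          f"(convolution law predicts {math.hypot(120, psf):5.1f} nm)")
# Wider PSFs inflate the same 120 nm objects: the ordering
# confocal > airyscan > gsted mirrors the modalities' resolutions.
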