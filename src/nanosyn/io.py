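"""Fixture-set writing and file round-trips.

Synthetic data sets stand in for the microscopy acquisitions: multi-channel
TIFF images per modality, ground-truth CSVs (synapses and clusters in nm),
localization-event CSVs, and a JSON manifest recording seeds and pixel
sizes so every file is reproducible bit-for-bit from its parameters.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .render import CHANNELS, MODALITIES, RenderedImage, render_scene
from .scene import Scene, SceneParams, generate_scene, \
    simulate_localization_events
from .smlm import stream_to_table

__all__ = ["FixtureConfig", "write_fixture_set", "read_image",
           "read_ground_truth"]


@dataclasses.dataclass(frozen=True)
class FixtureConfig:
    scene: SceneParams = SceneParams()
    modalities: tuple[str, ...] = ("confocal", "airyscan", "gsted")
    channels: tuple[str, ...] = CHANNELS
    smlm_n_frames: int = 400
    smlm_rate: float = 0.02
    smlm_precision_nm: float = 20.0


def _write_image(path: Path, image: RenderedImage) -> None:
    tifffile.imwrite(path, image.pixels.astype(np.float32),
                     photometric="minisblack")


def read_image(path, manifest_entry: dict) -> RenderedImage:
    """Load a fixture TIFF back into a calibrated RenderedImage."""
    pixels = tifffile.imread(path).astype(float)
    if pixels.ndim == 2:
        pixels = pixels[None]
    return RenderedImage(pixels, tuple(manifest_entry["channels"]),
                         tuple(manifest_entry["pixel_size_nm"]),
                         manifest_entry["modality"])


def read_ground_truth(out_dir) -> tuple[pd.DataFrame, pd.DataFrame]:
    out = Path(out_dir)
    return (pd.read_csv(out / "synapses_gt.csv"),
            pd.read_csv(out / "clusters_gt.csv"))


def write_fixture_set(out_dir, config: FixtureConfig | None = None) -> dict:
    """Generate one scene and write images, tables and a manifest.

    Returns the manifest (also written as ``manifest.json``): scene seed
    and parameters, one entry per modality image, the localization CSV and
    ground-truth CSV paths.  Running twice with the same config writes
    byte-identical CSVs.
    """
    config = config or FixtureConfig()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    scene = generate_scene(config.scene)

    images = {}
    for modality in config.modalities:
        img = render_scene(scene, modality, config.channels)
        path = out / f"image_{modality}.tif"
        _write_image(path, img)
        images[modality] = {
            "path": path.name, "modality": modality,
            "channels": list(img.channel_names),
            "pixel_size_nm": list(img.pixel_size_nm),
            "psf_fwhm_nm": MODALITIES[modality].psf_fwhm_nm,
        }

    scene.synapse_dataframe().to_csv(out / "synapses_gt.csv", index=False)
    scene.cluster_dataframe().to_csv(out / "clusters_gt.csv", index=False)

    stream = simulate_localization_events(
        scene, n_frames=config.smlm_n_frames,
        mean_events_per_cluster_per_frame=config.smlm_rate,
        precision_nm=config.smlm_precision_nm)
    table = stream_to_table(stream)
    table.to_csv(out / "localizations.csv")

    manifest = {
        "seed": config.scene.seed,
        "scene_params": {k: (list(v) if isinstance(v, tuple) else
                             dict(v) if isinstance(v, dict) else v)
                         for k, v in dataclasses.asdict(
                             config.scene).items()},
        "n_synapses": len(scene.synapses),
        "n_clusters": len(scene.clusters),
        "images": images,
        "ground_truth": {"synapses": "synapses_gt.csv",
                         "clusters": "clusters_gt.csv"},
        "localizations": {"path": "localizations.csv",
                          "n_frames": config.smlm_n_frames,
                          "n_events": len(table),
                          "precision_nm": config.smlm_precision_nm},
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
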