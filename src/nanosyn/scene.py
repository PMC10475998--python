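"""Ground-truth scenes of spinal-cord neuropil synapses.

A :class:`Scene` is a set of excitatory synapses in physical nanometre
coordinates.  Each synapse has a presynaptic terminal (VGLUT1- or
VGLUT2-positive) modelled as an ellipse and a postsynaptic density (PSD,
PSD95-positive) ellipse apposed to the terminal edge so the two partially
overlap -- overlap is what "synapse" means for the downstream
classification.  Protein clusters (diffraction-limited pTDP-43 puncta) are
placed inside terminal and PSD compartments with configurable per-compartment
occupancy probabilities.

Scenes are the common ground truth for every downstream stage: they can be
rendered as modality-specific images (:mod:`nanosyn.render`) or turned into
single-molecule localization event streams
(:func:`simulate_localization_events`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "COMPARTMENT_KINDS",
    "DEFAULT_OCCUPANCY",
    "SceneParams",
    "Ellipse",
    "SynapseGT",
    "ClusterGT",
    "Scene",
    "EmitterEventStream",
    "generate_scene",
    "simulate_localization_events",
    "make_spot_grid_scene",
]

#: The four synaptic compartment kinds tracked throughout the package.
COMPARTMENT_KINDS = ("vglut1_pre", "vglut2_pre", "vglut1_post", "vglut2_post")

#: Default probability that a compartment contains >=1 cluster, by kind.
#: Values are the study's healthy-control containment fractions.
DEFAULT_OCCUPANCY: Mapping[str, float] = {
    "vglut1_pre": 0.876,
    "vglut2_pre": 0.596,
    "vglut1_post": 0.462,
    "vglut2_post": 0.457,
}


def _check_mean_sd(name: str, value: tuple[float, float]) -> None:
    mean, sd = value
    if not (np.isfinite(mean) and np.isfinite(sd)) or mean <= 0 or sd < 0:
        raise ValueError(f"{name} must be (mean > 0, sd >= 0), got {value!r}")


@dataclass(frozen=True)
class SceneParams:
    """Parameters of a synthetic neuropil scene.

    Densities are terminals per 100 um^2; areas are (mean, sd) in um^2;
    cluster diameters are (mean, sd) in nm.  VGLUT1 terminals default to
    large and sparse, VGLUT2 terminals to small and four-fold more abundant.
    ``genotype_effect`` multiplicatively scales VGLUT1 terminal and
    VGLUT1-associated PSD areas (1.0 = healthy control; <1 models the
    disease-arm shrinkage of that synapse population).
    """

    field_size_um: float = 20.0
    density_vglut1: float = 4.0
    density_vglut2: float = 16.0
    vglut1_area_um2: tuple[float, float] = (0.8, 0.25)
    vglut2_area_um2: tuple[float, float] = (0.2, 0.06)
    psd_area_um2: tuple[float, float] = (0.15, 0.05)
    occupancy: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_OCCUPANCY)
    )
    clusters_per_occupied: float = 0.5
    cluster_diameter_nm: tuple[float, float] = (120.0, 25.0)
    vglut2_coexpression_frac: float = 0.1
    psd_overlap_frac: float = 0.25
    genotype_effect: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        for name in ("field_size_um", "density_vglut1", "density_vglut2",
                     "genotype_effect"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"{name} must be finite and > 0, got {v!r}")
        for name in ("vglut1_area_um2", "vglut2_area_um2", "psd_area_um2",
                     "cluster_diameter_nm"):
            _check_mean_sd(name, getattr(self, name))
        if self.clusters_per_occupied < 0 or not np.isfinite(
                self.clusters_per_occupied):
            raise ValueError("clusters_per_occupied must be >= 0")
        for kind, p in self.occupancy.items():
            if kind not in COMPARTMENT_KINDS:
                raise ValueError(f"unknown compartment kind {kind!r}")
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"occupancy[{kind!r}] must be in [0,1]")
        if not (0.0 < self.psd_overlap_frac <= 0.5):
            raise ValueError("psd_overlap_frac must be in (0, 0.5]")
        if not (0.0 <= self.vglut2_coexpression_frac <= 1.0):
            raise ValueError("vglut2_coexpression_frac must be in [0,1]")

    def with_seed(self, seed: int) -> "SceneParams":
        return replace(self, seed=int(seed))


@dataclass(frozen=True)
class Ellipse:
    """Filled ellipse in physical nm coordinates."""

    center: tuple[float, float]   # (x, y) nm
    semi_axes: tuple[float, float]  # (a, b) nm, a >= b
    orientation: float            # radians, major axis vs +x

    @property
    def area_um2(self) -> float:
        a, b = self.semi_axes
        return math.pi * a * b / 1e6

    def contains(self, x, y, margin: float = 0.0):
        """Membership test; ``margin`` expands (+) or shrinks (-) the axes."""
        a, b = self.semi_axes
        a, b = a + margin, b + margin
        dx = np.asarray(x, float) - self.center[0]
        dy = np.asarray(y, float) - self.center[1]
        c, s = math.cos(self.orientation), math.sin(self.orientation)
        u = dx * c + dy * s
        v = -dx * s + dy * c
        return (u / a) ** 2 + (v / b) ** 2 <= 1.0

    def boundary_radius(self, direction: float) -> float:
        """Distance from the center to the boundary along a world angle."""
        a, b = self.semi_axes
        psi = direction - self.orientation
        return a * b / math.hypot(b * math.cos(psi), a * math.sin(psi))

    def sample_inside(self, rng: np.random.Generator, n: int) -> np.ndarray:
        """Uniform points inside the ellipse, shape (n, 2)."""
        r = np.sqrt(rng.uniform(0.0, 1.0, n))
        t = rng.uniform(0.0, 2 * math.pi, n)
        u = r * np.cos(t) * self.semi_axes[0]
        v = r * np.sin(t) * self.semi_axes[1]
        c, s = math.cos(self.orientation), math.sin(self.orientation)
        x = self.center[0] + u * c - v * s
        y = self.center[1] + u * s + v * c
        return np.column_stack([x, y])


@dataclass(frozen=True)
class SynapseGT:
    id: int
    subtype: str                  # "VGLUT1" | "VGLUT2"
    terminal_ellipse: Ellipse
    psd_ellipse: Ellipse
    vglut2_coexpression: bool = False


@dataclass(frozen=True)
class ClusterGT:
    id: int
    center: tuple[float, float]   # nm
    diameter_nm: float
    compartment: str              # "presynaptic" | "postsynaptic"
    parent_synapse: int


@dataclass(frozen=True)
class Scene:
    params: SceneParams
    synapses: tuple[SynapseGT, ...]
    clusters: tuple[ClusterGT, ...]

    @property
    def field_size_nm(self) -> float:
        return self.params.field_size_um * 1000.0

    def synapse_dataframe(self) -> pd.DataFrame:
        rows = []
        for s in self.synapses:
            rows.append({
                "id": s.id, "subtype": s.subtype,
                "term_x_nm": s.terminal_ellipse.center[0],
                "term_y_nm": s.terminal_ellipse.center[1],
                "term_a_nm": s.terminal_ellipse.semi_axes[0],
                "term_b_nm": s.terminal_ellipse.semi_axes[1],
                "term_theta": s.terminal_ellipse.orientation,
                "psd_x_nm": s.psd_ellipse.center[0],
                "psd_y_nm": s.psd_ellipse.center[1],
                "psd_a_nm": s.psd_ellipse.semi_axes[0],
                "psd_b_nm": s.psd_ellipse.semi_axes[1],
                "psd_theta": s.psd_ellipse.orientation,
                "vglut2_coexpression": s.vglut2_coexpression,
            })
        return pd.DataFrame(rows)

    def cluster_dataframe(self) -> pd.DataFrame:
        rows = [{
            "id": c.id, "subtype": self.synapses[c.parent_synapse].subtype,
            "compartment": c.compartment,
            "x_nm": c.center[0], "y_nm": c.center[1], "z_nm": 0.0,
            "diameter_nm": c.diameter_nm,
        } for c in self.clusters]
        return pd.DataFrame(
            rows, columns=["id", "subtype", "compartment", "x_nm", "y_nm",
                           "z_nm", "diameter_nm"])

    def compartment_kind(self, cluster: ClusterGT) -> str:
        subtype = self.synapses[cluster.parent_synapse].subtype.lower()
        side = "pre" if cluster.compartment == "presynaptic" else "post"
        return f"{subtype}_{side}"


def _truncated_normal(rng, mean, sd, lo, n=None):
    """Normal draw re-sampled (then clipped) to stay above ``lo``."""
    x = rng.normal(mean, sd, n)
    bad = x <= lo
    tries = 0
    while np.any(bad) and tries < 20:
        x = np.where(bad, rng.normal(mean, sd, np.shape(x)), x)
        bad = x <= lo
        tries += 1
    return np.maximum(x, lo)


def _make_synapse(rng, sid, subtype, area_um2, psd_area_um2, overlap_frac,
                  field_nm):
    term_area_nm2 = area_um2 * 1e6
    aspect = rng.uniform(1.0, 2.0)
    b = math.sqrt(term_area_nm2 / (math.pi * aspect))
    a = aspect * b
    theta = rng.uniform(0.0, math.pi)

    psd_area_nm2 = psd_area_um2 * 1e6
    psd_aspect = rng.uniform(1.5, 3.0)
    pb = math.sqrt(psd_area_nm2 / (math.pi * psd_aspect))
    pa = psd_aspect * pb

    # Keep the whole synapse (terminal + apposed PSD) inside the field.
    margin = a + 2 * pa + 50.0
    lo, hi = margin, field_nm - margin
    if lo >= hi:
        raise ValueError(
            "field_size_um too small for the configured structure sizes")
    cx, cy = rng.uniform(lo, hi, 2)

    phi = rng.uniform(0.0, 2 * math.pi)   # apposition direction
    terminal = Ellipse((cx, cy), (a, b), theta)
    # PSD major axis tangential to the terminal boundary.
    psd_theta = (phi + math.pi / 2) % math.pi
    psd_tmp = Ellipse((0.0, 0.0), (pa, pb), psd_theta)
    r_t = terminal.boundary_radius(phi)
    # Depth of PSD penetration into the terminal ~ 2*overlap_frac*r_p.
    r_p = psd_tmp.boundary_radius(phi)
    d = r_t + (1.0 - 2.0 * overlap_frac) * r_p
    psd = Ellipse((cx + d * math.cos(phi), cy + d * math.sin(phi)),
                  (pa, pb), psd_theta)
    return SynapseGT(sid, subtype, terminal, psd)


def generate_scene(params: SceneParams) -> Scene:
    """Draw a ground-truth scene from :class:`SceneParams`.

    Synapse counts are Poisson in the field area at the configured
    densities; compartment areas are (truncated) normal; cluster presence
    per compartment is Bernoulli with the per-kind occupancy probability and
    occupied compartments hold ``1 + Poisson(clusters_per_occupied)``
    clusters placed uniformly inside the compartment ellipse.  Deterministic
    for a fixed seed.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    field_nm = params.field_size_um * 1000.0
    area_100um2 = params.field_size_um ** 2 / 100.0

    n1 = rng.poisson(params.density_vglut1 * area_100um2)
    n2 = rng.poisson(params.density_vglut2 * area_100um2)

    synapses: list[SynapseGT] = []
    sid = 0
    for subtype, n, (am, asd) in (("VGLUT1", n1, params.vglut1_area_um2),
                                  ("VGLUT2", n2, params.vglut2_area_um2)):
        areas = _truncated_normal(rng, am, asd, 0.02 * am, n)
        pm, psd = params.psd_area_um2
        psd_areas = _truncated_normal(rng, pm, psd, 0.02 * pm, n)
        if subtype == "VGLUT1" and params.genotype_effect != 1.0:
            areas = areas * params.genotype_effect
            psd_areas = psd_areas * params.genotype_effect
        for i in range(n):
            syn = _make_synapse(rng, sid, subtype, areas[i], psd_areas[i],
                                params.psd_overlap_frac, field_nm)
            if subtype == "VGLUT1":
                coex = rng.uniform() < params.vglut2_coexpression_frac
                syn = replace(syn, vglut2_coexpression=bool(coex))
            synapses.append(syn)
            sid += 1

    occupancy = {k: float(params.occupancy.get(k, 0.0))
                 for k in COMPARTMENT_KINDS}
    dm, dsd = params.cluster_diameter_nm
    clusters: list[ClusterGT] = []
    cid = 0
    for syn in synapses:
        sub = syn.subtype.lower()
        for side, compartment, ellipse in (
                ("pre", "presynaptic", syn.terminal_ellipse),
                ("post", "postsynaptic", syn.psd_ellipse)):
            p = occupancy[f"{sub}_{side}"]
            if p <= 0.0 or rng.uniform() >= p:
                continue
            n_clusters = 1 + rng.poisson(params.clusters_per_occupied)
            pts = ellipse.sample_inside(rng, n_clusters)
            diams = _truncated_normal(rng, dm, dsd, 20.0, n_clusters)
            for j in range(n_clusters):
                clusters.append(ClusterGT(
                    cid, (float(pts[j, 0]), float(pts[j, 1])),
                    float(diams[j]), compartment, syn.id))
                cid += 1

    return Scene(params, tuple(synapses), tuple(clusters))


def make_spot_grid_scene(n_spots: int, diameter_nm: float = 120.0,
                         diameter_sd_nm: float = 0.0,
                         spacing_um: float = 2.0, seed: int = 0,
                         jitter_nm: float = 200.0) -> Scene:
    """Scene of isolated clusters on a jittered grid, for spot-sizing work.

    Each cluster sits inside its own (large) dummy terminal so the scene
    satisfies the parent-compartment invariant; the cluster channel is the
    one of interest.
    """
    side = int(math.ceil(math.sqrt(n_spots)))
    field_um = spacing_um * (side + 1)
    rng = np.random.default_rng(seed)
    params = SceneParams(field_size_um=field_um, density_vglut1=0.0001,
                         density_vglut2=0.0001, seed=seed)
    synapses, clusters = [], []
    k = 0
    for i in range(side):
        for j in range(side):
            if k >= n_spots:
                break
            cx = (i + 1) * spacing_um * 1000.0 + rng.uniform(-jitter_nm,
                                                             jitter_nm)
            cy = (j + 1) * spacing_um * 1000.0 + rng.uniform(-jitter_nm,
                                                             jitter_nm)
            term = Ellipse((cx, cy), (600.0, 500.0), 0.0)
            psd = Ellipse((cx + 550.0, cy), (250.0, 120.0), math.pi / 2)
            synapses.append(SynapseGT(k, "VGLUT1", term, psd))
            d = diameter_nm if diameter_sd_nm == 0 else float(
                _truncated_normal(rng, diameter_nm, diameter_sd_nm, 20.0))
            clusters.append(ClusterGT(k, (cx, cy), d, "presynaptic", k))
            k += 1
    return Scene(params, tuple(synapses), tuple(clusters))


@dataclass(frozen=True)
class EmitterEventStream:
    """Stochastic binding/blinking events from the clusters of a scene.

    ``true_xy`` is the emitter position (uniform within the cluster disc);
    ``detected_xy`` adds isotropic Gaussian localization error.
    """

    frame: np.ndarray          # int, 1-based, shape (n,)
    true_xy: np.ndarray        # (n, 2) nm
    detected_xy: np.ndarray    # (n, 2) nm
    photons: np.ndarray        # (n,)
    n_frames: int
    exposure_ms: float = 50.0
    precision_nm: float = 20.0

    def __len__(self) -> int:
        return len(self.frame)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({
            "frame": self.frame,
            "x_nm": self.detected_xy[:, 0],
            "y_nm": self.detected_xy[:, 1],
            "photons": self.photons,
        })


def simulate_localization_events(
        scene: Scene, n_frames: int = 4000,
        mean_events_per_cluster_per_frame: float = 0.02,
        precision_nm: float = 20.0, seed: int | None = None,
        exposure_ms: float = 50.0,
        photon_lognorm: tuple[float, float] = (math.log(600.0), 0.5),
) -> EmitterEventStream:
    """Simulate DNA-PAINT-style binding events for every cluster in a scene.

    Per frame each cluster emits a Poisson number of events (rate
    ``mean_events_per_cluster_per_frame``), positioned uniformly within the
    cluster disc and detected with isotropic Gaussian error of scale
    ``precision_nm``.  Photon counts are log-normal.
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    if mean_events_per_cluster_per_frame < 0 or not np.isfinite(
            mean_events_per_cluster_per_frame):
        raise ValueError("event rate must be >= 0 and finite")
    if precision_nm < 0:
        raise ValueError("precision_nm must be >= 0")

    rng = np.random.default_rng(scene.params.seed if seed is None else seed)
    frames_list, true_list = [], []
    lam = mean_events_per_cluster_per_frame * n_frames
    for c in scene.clusters:
        n = int(rng.poisson(lam))
        if n == 0:
            continue
        fr = rng.integers(1, n_frames + 1, n)
        r = (c.diameter_nm / 2.0) * np.sqrt(rng.uniform(0, 1, n))
        t = rng.uniform(0, 2 * math.pi, n)
        xy = np.column_stack([c.center[0] + r * np.cos(t),
                              c.center[1] + r * np.sin(t)])
        frames_list.append(fr)
        true_list.append(xy)

    if frames_list:
        frame = np.concatenate(frames_list)
        true_xy = np.vstack(true_list)
    else:
        frame = np.empty(0, dtype=int)
        true_xy = np.empty((0, 2))
    order = np.argsort(frame, kind="stable")
    frame, true_xy = frame[order], true_xy[order]
    detected = true_xy + rng.normal(0.0, precision_nm, true_xy.shape)
    mu, sigma = photon_lognorm
    photons = rng.lognormal(mu, sigma, len(frame))
    return EmitterEventStream(frame.astype(int), true_xy, detected, photons,
                              int(n_frames), float(exposure_ms),
                              float(precision_nm))
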