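"""Single-molecule localization microscopy analysis chain.

Frame preprocessing (rolling-ball background subtraction), 2D Gaussian
peak fitting with Thompson-style precision estimates, quality filtering
(signal strength, photon count, fit precision), DBSCAN clustering of the
localizations, cluster geometry, association of clusters with segmented
synaptic terminals, and Fourier ring correlation (FRC) resolution.

Defaults follow the standard DNA-PAINT workflow for synaptic protein
clusters: filters signal >= 20, photons >= 50, precision <= 40 nm (all
inclusive); DBSCAN with eps = 40 nm and minPts = 5; FRC from an odd/even
frame split rendered at a 10 nm super-resolution pixel with the fixed 1/7
threshold.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from scipy.optimize import curve_fit
from scipy.spatial.distance import pdist
from sklearn.cluster import DBSCAN

from .scene import EmitterEventStream
from .segment import LabeledMask, rolling_ball_background

__all__ = ["LocalizationTable", "SmlmCluster", "FrcResult",
           "subtract_background_frames", "fit_peaks", "filter_localizations",
           "stream_to_table", "dbscan_cluster", "cluster_geometry",
           "associate_clusters_with_synapses", "association_contingency",
           "frc_resolution"]

_LOC_COLUMNS = ["frame", "x_nm", "y_nm", "photons", "signal", "precision_nm"]


@dataclass(frozen=True)
class LocalizationTable:
    """Table of localization events with quality metrics.

    ``rows`` has columns frame (1-based int), x_nm, y_nm, photons, signal
    (fitted amplitude / residual noise), precision_nm.
    """

    rows: pd.DataFrame
    pixel_size_nm: float
    n_frames: int

    def __post_init__(self):
        missing = [c for c in _LOC_COLUMNS if c not in self.rows.columns]
        if missing:
            raise ValueError(f"localization table missing columns {missing}")

    def __len__(self) -> int:
        return len(self.rows)

    @property
    def xy(self) -> np.ndarray:
        return self.rows[["x_nm", "y_nm"]].to_numpy(float)

    def to_csv(self, path) -> None:
        self.rows.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, pixel_size_nm: float = 107.0,
                 n_frames: int | None = None) -> "LocalizationTable":
        """Read the CSV dialect ``frame,x_nm,y_nm,photons[,signal,precision_nm]``.

        Tolerant to extra columns; missing quality columns are filled with
        permissive values so unfiltered tables pass through.
        """
        df = pd.read_csv(path)
        if "signal" not in df.columns:
            df["signal"] = np.inf
        if "precision_nm" not in df.columns:
            df["precision_nm"] = 0.0
        df = df[_LOC_COLUMNS + [c for c in df.columns
                                if c not in _LOC_COLUMNS]]
        nf = int(df["frame"].max()) if n_frames is None and len(df) else \
            (n_frames or 1)
        return cls(df.reset_index(drop=True), float(pixel_size_nm), int(nf))


def subtract_background_frames(frames: np.ndarray,
                               radius_px: int = 12) -> np.ndarray:
    """Rolling-ball background subtraction applied per frame."""
    stack = np.asarray(frames, float)
    if stack.ndim == 2:
        stack = stack[None]
    out = np.empty_like(stack)
    for i, frame in enumerate(stack):
        out[i] = frame - rolling_ball_background(frame, radius_px)
    return np.maximum(out, 0.0)


def _gauss2d(coords, amplitude, x0, y0, sigma, offset):
    x, y = coords
    return (offset + amplitude *
            np.exp(-((x - x0) ** 2 + (y - y0) ** 2) / (2 * sigma ** 2))
            ).ravel()


def fit_peaks(frames: np.ndarray, pixel_size_nm: float = 107.0,
              detection_threshold: float = 30.0, window: int = 7,
              psf_sigma_nm: float | None = None) -> LocalizationTable:
    """Detect and Gaussian-fit single-molecule events in a frame stack.

    Per frame, local maxima above ``detection_threshold`` are fitted with a
    2D symmetric Gaussian in a ``window`` x ``window`` crop.  Photons are
    the fitted integrated intensity (2*pi*A*sigma^2, counts taken as
    photons); precision follows the Thompson-style closed form
    sqrt((sigma_psf^2 + a^2/12) / N) with ``a`` the pixel size; signal
    strength is the fitted amplitude over the residual noise SD.  Diverged
    fits are dropped (counted in the table's ``attrs['n_failed']``).
    """
    stack = np.asarray(frames, float)
    if stack.ndim == 2:
        stack = stack[None]
    half = window // 2
    records, n_failed = [], 0
    yy, xx = np.mgrid[0:window, 0:window].astype(float)
    for t, frame in enumerate(stack):
        if frame.size == 0:
            continue
        local_max = ndi.maximum_filter(frame, size=window, mode="nearest")
        cand = np.argwhere((frame == local_max) &
                           (frame > detection_threshold))
        for r, c in cand:
            if not (half <= r < frame.shape[0] - half and
                    half <= c < frame.shape[1] - half):
                continue
            crop = frame[r - half:r + half + 1, c - half:c + half + 1]
            p0 = (float(crop.max() - crop.min()), float(half), float(half),
                  1.2, float(crop.min()))
            try:
                popt, _ = curve_fit(
                    _gauss2d, (xx, yy), crop.ravel(), p0=p0, maxfev=2000,
                    bounds=([0, -1, -1, 0.3, -np.inf],
                            [np.inf, window, window, window, np.inf]))
            except (RuntimeError, ValueError):
                n_failed += 1
                continue
            amp, x0, y0, sigma, offset = map(float, popt)
            resid = crop.ravel() - _gauss2d((xx, yy), *popt)
            noise = float(np.std(resid))
            photons = 2.0 * math.pi * amp * sigma ** 2
            if photons <= 0:
                n_failed += 1
                continue
            s_nm = (psf_sigma_nm if psf_sigma_nm is not None
                    else sigma * pixel_size_nm)
            precision = math.sqrt(
                (s_nm ** 2 + pixel_size_nm ** 2 / 12.0) / photons)
            records.append({
                "frame": t + 1,
                "x_nm": (c - half + x0 + 0.5) * pixel_size_nm,
                "y_nm": (r - half + y0 + 0.5) * pixel_size_nm,
                "photons": photons,
                "signal": amp / noise if noise > 0 else np.inf,
                "precision_nm": precision,
            })
    df = pd.DataFrame(records, columns=_LOC_COLUMNS)
    df.attrs["n_failed"] = n_failed
    return LocalizationTable(df, float(pixel_size_nm), int(len(stack)))


def stream_to_table(stream: EmitterEventStream,
                    pixel_size_nm: float = 107.0) -> LocalizationTable:
    """Build a localization table directly from a simulated event stream.

    Quality columns are derived from the stream: precision scales as
    1/sqrt(photons) around the stream's nominal localization error, and
    signal strength is proportional to photons (amplitude-over-noise proxy
    at fixed camera noise).
    """
    photons = np.asarray(stream.photons, float)
    if len(photons):
        ref = float(np.median(photons))
        precision = stream.precision_nm * np.sqrt(ref / np.maximum(photons, 1))
        signal = photons / 20.0
    else:
        precision = np.empty(0)
        signal = np.empty(0)
    df = pd.DataFrame({
        "frame": stream.frame, "x_nm": stream.detected_xy[:, 0],
        "y_nm": stream.detected_xy[:, 1], "photons": photons,
        "signal": signal, "precision_nm": precision,
    }, columns=_LOC_COLUMNS)
    return LocalizationTable(df, float(pixel_size_nm), stream.n_frames)


def filter_localizations(table: LocalizationTable, min_signal: float = 20.0,
                         min_photons: float = 50.0,
                         max_precision_nm: float = 40.0) -> LocalizationTable:
    """Quality filter; all three thresholds inclusive, row order preserved."""
    df = table.rows
    keep = ((df["signal"] >= min_signal) & (df["photons"] >= min_photons) &
            (df["precision_nm"] <= max_precision_nm))
    return replace(table, rows=df[keep].reset_index(drop=True))


@dataclass(frozen=True)
class SmlmCluster:
    cluster_id: int
    member_ids: np.ndarray      # row indices into the source table
    n_locs: int
    centroid_nm: tuple[float, float]
    diameter_nm: float
    synapse_assignment: int | None = None   # terminal label, None = outside
    subtype: str | None = None


def cluster_geometry(points_nm: np.ndarray,
                     precision_nm: np.ndarray | float | None = None,
                     method: str = "rms") -> tuple[float,
                                                   tuple[float, float]]:
    """(diameter, centroid) of a localization cluster.

    ``method="rms"`` (default) estimates the physical diameter of the
    underlying structure as ``2*sqrt(2) * sqrt(S/(m-1) - 2*mean(prec^2))``
    with ``S`` the total squared deviation from the member mean -- for
    localizations drawn uniformly from a disc this is unbiased for the disc
    diameter, and subtracting the mean squared localization precision
    removes the noise inflation that would otherwise dominate small
    clusters.  ``method="max_pairwise"`` returns the maximum pairwise
    member distance (no precision correction).  Both are translation- and
    rotation-invariant; the centroid is the member mean.
    """
    pts = np.asarray(points_nm, float)
    if len(pts) == 0:
        raise ValueError("empty cluster")
    centroid = (float(pts[:, 0].mean()), float(pts[:, 1].mean()))
    m = len(pts)
    if m == 1:
        return 0.0, centroid
    if method == "max_pairwise":
        return float(pdist(pts).max()), centroid
    if method != "rms":
        raise ValueError("method must be 'rms' or 'max_pairwise'")
    dev = pts - pts.mean(axis=0)
    var2d = float((dev ** 2).sum()) / (m - 1)
    if precision_nm is not None:
        prec2 = float(np.mean(np.square(precision_nm)))
        var2d = max(var2d - 2.0 * prec2, 0.0)
    return float(2.0 * math.sqrt(2.0) * math.sqrt(var2d)), centroid


def dbscan_cluster(table: LocalizationTable, eps_nm: float = 40.0,
                   min_pts: int = 5,
                   diameter_method: str = "rms") -> list[SmlmCluster]:
    """DBSCAN on (x, y) with Euclidean metric; noise points are discarded.

    ``min_pts`` counts the point itself, so 5 mutually close points form
    one cluster at the default setting.  Clusters are returned ordered by
    first-discovered core point (sklearn's deterministic row-order
    traversal) and renumbered 0..k-1.  Cluster diameters use
    :func:`cluster_geometry` with the members' precision estimates.
    """
    if len(table) == 0:
        return []
    xy = table.xy
    prec = table.rows["precision_nm"].to_numpy(float)
    labels = DBSCAN(eps=eps_nm, min_samples=min_pts).fit(xy).labels_
    clusters = []
    for cid in range(labels.max() + 1):
        members = np.flatnonzero(labels == cid)
        diameter, centroid = cluster_geometry(xy[members], prec[members],
                                              method=diameter_method)
        clusters.append(SmlmCluster(cid, members, int(len(members)),
                                    centroid, diameter))
    return clusters


def associate_clusters_with_synapses(clusters: list[SmlmCluster],
                                     terminal_mask: LabeledMask,
                                     subtype: str | None = None
                                     ) -> tuple[list[SmlmCluster],
                                                pd.DataFrame]:
    """Assign clusters to the terminal whose foreground holds their centroid.

    nm -> pixel mapping: pixel j covers [j*p, (j+1)*p).  Returns the
    clusters with assignments filled in plus a per-terminal table with a
    contains flag and cluster count.
    """
    labels = terminal_mask.labels
    if labels.ndim != 2:
        raise ValueError("terminal mask must be 2D")
    py, px = terminal_mask.pixel_size_nm[-2], terminal_mask.pixel_size_nm[-1]
    out = []
    counts = {o.label: 0 for o in terminal_mask.objects}
    for cl in clusters:
        j = int(cl.centroid_nm[0] // px)
        i = int(cl.centroid_nm[1] // py)
        lab = None
        if 0 <= i < labels.shape[0] and 0 <= j < labels.shape[1]:
            v = int(labels[i, j])
            if v > 0:
                lab = v
                counts[v] = counts.get(v, 0) + 1
        out.append(replace(cl, synapse_assignment=lab, subtype=subtype))
    per_terminal = pd.DataFrame(
        [{"label": lab, "n_clusters": n, "contains": n > 0}
         for lab, n in sorted(counts.items())],
        columns=["label", "n_clusters", "contains"])
    return out, per_terminal


def association_contingency(per_terminal_by_subtype: dict[str, pd.DataFrame]
                            ) -> pd.DataFrame:
    """2 x k contingency of terminals with / without clusters per subtype."""
    data = {}
    for subtype, tbl in per_terminal_by_subtype.items():
        with_c = int(tbl["contains"].sum())
        data[subtype] = [with_c, len(tbl) - with_c]
    return pd.DataFrame(data, index=["with_clusters", "without_clusters"]).T


@dataclass(frozen=True)
class FrcResult:
    resolution_nm: float     # NaN when unresolved
    resolved: bool
    spatial_freq_per_nm: np.ndarray
    frc: np.ndarray
    threshold: float = 1.0 / 7.0


def _render_histogram(xy: np.ndarray, n: int, pixel_nm: float) -> np.ndarray:
    edges = np.arange(n + 1) * pixel_nm
    h, _, _ = np.histogram2d(xy[:, 1], xy[:, 0], bins=(edges, edges))
    return h


def frc_resolution(table: LocalizationTable, render_pixel_nm: float = 10.0,
                   split_rule: str = "odd_even",
                   smooth_window: int = 5) -> FrcResult:
    """Fourier ring correlation resolution of a localization data set.

    The table is split into two statistically independent halves (odd vs
    even frames by default, or odd/even rows), each half is rendered as a
    2D histogram at ``render_pixel_nm``, and the ring-wise correlation of
    their Fourier transforms is smoothed and scanned for its first crossing
    of the fixed 1/7 threshold; the inverse of that spatial frequency is
    the resolution.  If the curve never drops below 1/7 before Nyquist the
    data set is reported as unresolved (NaN resolution).
    """
    if len(table) < 2:
        raise ValueError("need >= 2 localizations for FRC")
    df = table.rows
    if split_rule == "odd_even":
        sel = (df["frame"].to_numpy() % 2) == 1
    elif split_rule == "odd_even_rows":
        sel = (np.arange(len(df)) % 2) == 0
    else:
        raise ValueError("split_rule must be 'odd_even' or 'odd_even_rows'")
    xy = table.xy
    a, b = xy[sel], xy[~sel]
    if len(a) == 0 or len(b) == 0:
        raise ValueError("degenerate split: one half has no localizations")

    n = int(math.ceil(max(xy[:, 0].max(), xy[:, 1].max()) / render_pixel_nm))
    n = max(n, 16)
    h1 = _render_histogram(a, n, render_pixel_nm)
    h2 = _render_histogram(b, n, render_pixel_nm)

    f1 = np.fft.fftshift(np.fft.fft2(h1))
    f2 = np.fft.fftshift(np.fft.fft2(h2))
    cy = n // 2
    yy, xx = np.indices((n, n))
    r = np.hypot(yy - cy, xx - cy).astype(int)
    n_rings = n // 2
    num = np.bincount(r.ravel(), (f1 * np.conj(f2)).real.ravel(),
                      minlength=n_rings)[:n_rings]
    d1 = np.bincount(r.ravel(), np.abs(f1).ravel() ** 2,
                     minlength=n_rings)[:n_rings]
    d2 = np.bincount(r.ravel(), np.abs(f2).ravel() ** 2,
                     minlength=n_rings)[:n_rings]
    with np.errstate(invalid="ignore", divide="ignore"):
        frc = num / np.sqrt(d1 * d2)
    frc = np.nan_to_num(frc, nan=0.0)
    if smooth_window > 1:
        frc = ndi.uniform_filter1d(frc, smooth_window, mode="nearest")
    freq = np.arange(n_rings) / (n * render_pixel_nm)

    thr = 1.0 / 7.0
    below = np.flatnonzero(frc[1:] < thr) + 1
    if len(below) == 0:
        return FrcResult(math.nan, False, freq, frc)
    k = below[0]
    # linear interpolation of the crossing between rings k-1 and k
    f_lo, f_hi = frc[k - 1], frc[k]
    t = 0.0 if f_lo == f_hi else (f_lo - thr) / (f_lo - f_hi)
    fc = freq[k - 1] + t * (freq[k] - freq[k - 1])
    if fc <= 0:
        return FrcResult(math.nan, False, freq, frc)
    return FrcResult(float(1.0 / fc), True, freq, frc)
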