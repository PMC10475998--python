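"""Localization pipeline: fitting, filtering, DBSCAN, geometry, FRC."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform

import nanosyn as ns
from nanosyn.segment import SegmentationParams
from nanosyn.smlm import LocalizationTable, cluster_geometry


def make_table(xy, frame=None, photons=600.0, signal=30.0, precision=10.0,
               n_frames=100):
    xy = np.asarray(xy, float)
    df = pd.DataFrame({
        "frame": frame if frame is not None else np.ones(len(xy), int),
        "x_nm": xy[:, 0], "y_nm": xy[:, 1],
        "photons": np.broadcast_to(photons, len(xy)).copy(),
        "signal": np.broadcast_to(signal, len(xy)).copy(),
        "precision_nm": np.broadcast_to(precision, len(xy)).copy(),
    })
    return LocalizationTable(df, 107.0, n_frames)


def brute_dbscan(xy, eps, min_pts):
    """Reference DBSCAN: O(n^2) neighbourhoods + BFS cluster expansion."""
    n = len(xy)
    if n == 0:
        return np.full(0, -1)
    d = squareform(pdist(xy)) if n > 1 else np.zeros((1, 1))
    neighbors = [np.flatnonzero(d[i] <= eps) for i in range(n)]
    core = np.array([len(nb) >= min_pts for nb in neighbors])
    labels = np.full(n, -1)
    cid = 0
    for i in range(n):
        if not core[i] or labels[i] != -1:
            continue
        labels[i] = cid
        stack = [i]
        while stack:
            j = stack.pop(0)
            for k in neighbors[j]:
                if labels[k] == -1:
                    labels[k] = cid
                    if core[k]:
                        stack.append(k)
        cid += 1
    return labels


class TestBackgroundSubtraction:
    def test_constant_frame_goes_to_zero(self):
        out = ns.subtract_background_frames(np.full((1, 30, 30), 11.0), 5)
        assert np.allclose(out, 0.0, atol=1e-6)

    def test_huge_radius_acts_as_global_min(self, rng):
        frame = rng.uniform(10, 12, (20, 20))
        out = ns.subtract_background_frames(frame, radius_px=500)
        expect = frame - frame.min()
        assert np.allclose(out[0], expect, atol=0.5)

    def test_sloped_background_improves_contrast(self):
        yy, xx = np.mgrid[0:40, 0:40].astype(float)
        frame = 5.0 + 1.0 * xx
        frame[20, 20] += 80.0
        out = ns.subtract_background_frames(frame, radius_px=12)[0]
        ratio_before = frame[20, 20] / np.median(frame)
        ratio_after = out[20, 20] / max(np.median(out), 1e-9)
        assert ratio_after > ratio_before


class TestPeakFitting:
    @staticmethod
    def emitter_frame(shape=(32, 32), x0=15.3, y0=12.7, sigma=1.3,
                      amp=200.0):
        yy, xx = np.mgrid[0:shape[0], 0:shape[1]].astype(float)
        img = amp * np.exp(-(((xx - x0) ** 2 + (yy - y0) ** 2) /
                             (2 * sigma ** 2)))
        return img, 2 * math.pi * amp * sigma ** 2

    def test_noiseless_emitter_recovered(self):
        frame, photons = self.emitter_frame()
        tab = ns.fit_peaks(frame, pixel_size_nm=107.0,
                           detection_threshold=50)
        assert len(tab) == 1
        row = tab.rows.iloc[0]
        assert row.x_nm / 107.0 - 0.5 == pytest.approx(15.3, abs=0.05)
        assert row.y_nm / 107.0 - 0.5 == pytest.approx(12.7, abs=0.05)
        assert row.photons == pytest.approx(photons, rel=0.02)

    def test_empty_frame_no_localizations(self):
        tab = ns.fit_peaks(np.zeros((24, 24)), detection_threshold=5)
        assert len(tab) == 0

    def test_monte_carlo_error_within_twice_thompson(self, rng):
        """Observed localization RMSE under shot noise stays within 2x the
        Thompson-style precision prediction."""
        frame, _ = self.emitter_frame(amp=150.0)
        errs, preds = [], []
        for _ in range(60):
            noisy = rng.poisson(frame + 5.0) - 5.0
            tab = ns.fit_peaks(noisy.astype(float), pixel_size_nm=107.0,
                               detection_threshold=60,
                               psf_sigma_nm=1.3 * 107.0)
            if len(tab) != 1:
                continue
            row = tab.rows.iloc[0]
            err = math.hypot(row.x_nm - (15.3 + 0.5) * 107.0,
                             row.y_nm - (12.7 + 0.5) * 107.0)
            errs.append(err)
            preds.append(row.precision_nm)
        assert len(errs) > 40
        rmse_1d = np.sqrt(np.mean(np.square(errs)) / 2.0)
        assert rmse_1d <= 2.0 * np.mean(preds)


class TestFiltering:
    def test_boundary_rows_inclusive(self):
        tab = make_table([[0, 0], [10, 10], [20, 20]],
                         photons=[50.0, 49.0, 600.0],
                         signal=[20.0, 25.0, 30.0],
                         precision=[40.0, 30.0, 41.0])
        kept = ns.filter_localizations(tab)
        # row 0 sits exactly on every threshold -> kept; 1 fails photons;
        # 2 fails precision
        assert kept.rows["x_nm"].tolist() == [0.0]

    def test_matches_predicate_oracle_and_idempotent(self, rng):
        xy = rng.uniform(0, 1000, (200, 2))
        tab = make_table(xy, photons=rng.uniform(10, 200, 200),
                         signal=rng.uniform(0, 50, 200),
                         precision=rng.uniform(5, 80, 200))
        kept = ns.filter_localizations(tab)
        df = tab.rows
        expect = df[(df.signal >= 20) & (df.photons >= 50) &
                    (df.precision_nm <= 40)]
        assert kept.rows["x_nm"].tolist() == expect["x_nm"].tolist()
        again = ns.filter_localizations(kept)
        assert again.rows.equals(kept.rows)


class TestDbscan:
    def test_five_close_points_one_cluster(self):
        xy = [[0, 0], [10, 0], [0, 10], [10, 10], [5, 5]]
        clusters = ns.dbscan_cluster(make_table(xy))
        assert len(clusters) == 1 and clusters[0].n_locs == 5

    def test_four_points_below_min_pts(self):
        xy = [[0, 0], [10, 0], [0, 10], [10, 10]]
        assert ns.dbscan_cluster(make_table(xy)) == []

    def test_empty_table(self):
        assert ns.dbscan_cluster(make_table(np.empty((0, 2)))) == []

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(20):
            n = rng.integers(10, 100)
            xy = rng.uniform(0, 400, (n, 2))
            clusters = ns.dbscan_cluster(make_table(xy))
            ref = brute_dbscan(xy, 40.0, 5)
            got = np.full(n, -1)
            for c in clusters:
                got[c.member_ids] = c.cluster_id
            # same partition of core/member points up to label renaming
            assert (got >= 0).sum() == (ref >= 0).sum()
            for cid in range(ref.max() + 1):
                members = np.flatnonzero(ref == cid)
                core_labels = got[members]
                assert len(set(core_labels[core_labels >= 0])) == 1

    def test_core_membership_invariant_to_row_order(self, rng):
        xy = rng.uniform(0, 200, (60, 2))
        perm = rng.permutation(60)
        a = ns.dbscan_cluster(make_table(xy))
        b = ns.dbscan_cluster(make_table(xy[perm]))
        na = sum(c.n_locs for c in a)
        nb = sum(c.n_locs for c in b)
        assert len(a) == len(b) and na == nb


class TestClusterGeometry:
    def test_coincident_points_zero_diameter(self):
        pts = np.zeros((5, 2))
        for method in ("rms", "max_pairwise"):
            d, c = cluster_geometry(pts, method=method)
            assert d == 0.0 and c == (0.0, 0.0)

    def test_two_endpoints_and_midpoints(self):
        pts = np.array([[-50, 0], [50, 0], [0, 0], [0, 0], [0, 0]], float)
        d_max, _ = cluster_geometry(pts, method="max_pairwise")
        d_rms, _ = cluster_geometry(pts, method="rms")
        assert d_max == pytest.approx(100.0)
        assert d_rms == pytest.approx(100.0)

    def test_max_pairwise_matches_exhaustive_oracle(self, rng):
        pts = rng.uniform(0, 300, (20, 2))
        d, _ = cluster_geometry(pts, method="max_pairwise")
        best = max(math.dist(p, q) for p in pts for q in pts)
        assert d == pytest.approx(best)

    def test_translation_rotation_invariance(self, rng):
        pts = rng.uniform(0, 100, (15, 2))
        th = 0.7
        R = np.array([[math.cos(th), -math.sin(th)],
                      [math.sin(th), math.cos(th)]])
        moved = pts @ R.T + [1000.0, -500.0]
        for method in ("rms", "max_pairwise"):
            d0, _ = cluster_geometry(pts, method=method)
            d1, _ = cluster_geometry(moved, method=method)
            assert d1 == pytest.approx(d0, rel=1e-9)

    def test_precision_correction_debiases_disc_diameter(self, rng):
        """RMS diameters of noisy localizations of a 55 nm disc are
        unbiased after subtracting the localization variance."""
        ds = []
        for _ in range(300):
            m = 12
            r = 27.5 * np.sqrt(rng.uniform(0, 1, m))
            t = rng.uniform(0, 2 * math.pi, m)
            pts = np.c_[r * np.cos(t), r * np.sin(t)] + \
                rng.normal(0, 20.0, (m, 2))
            d, _ = cluster_geometry(pts, precision_nm=20.0)
            ds.append(d)
        assert np.median(ds) == pytest.approx(55.0, rel=0.15)


class TestAssociation:
    @staticmethod
    def terminal_mask():
        labels = np.zeros((10, 10), int)
        labels[2:6, 2:6] = 1
        objects = (ns.ObjectRecord(1, 16, 16 * 0.107 ** 2, (3.5, 3.5),
                                   (2, 2, 6, 6)),)
        return ns.LabeledMask(labels, objects, (107.0, 107.0))

    def _cluster(self, x, y):
        return ns.SmlmCluster(0, np.array([0]), 5, (x, y), 50.0)

    def test_centroid_inside_assigned(self):
        mask = self.terminal_mask()
        out, table = ns.associate_clusters_with_synapses(
            [self._cluster(3.0 * 107, 4.0 * 107)], mask)
        assert out[0].synapse_assignment == 1
        assert bool(table.loc[0, "contains"])

    def test_centroid_outside_unassigned(self):
        mask = self.terminal_mask()
        out, table = ns.associate_clusters_with_synapses(
            [self._cluster(9.5 * 107, 9.5 * 107)], mask)
        assert out[0].synapse_assignment is None
        assert not bool(table.loc[0, "contains"])

    def test_contingency_layout(self):
        t1 = pd.DataFrame({"label": [1, 2], "n_clusters": [1, 0],
                           "contains": [True, False]})
        t2 = pd.DataFrame({"label": [1], "n_clusters": [0],
                           "contains": [False]})
        tab = ns.association_contingency({"VGLUT1": t1, "VGLUT2": t2})
        assert tab.loc["VGLUT1"].tolist() == [1, 1]
        assert tab.loc["VGLUT2"].tolist() == [0, 1]


class TestFrc:
    def test_identical_halves_unresolved(self, rng):
        xy = rng.uniform(0, 3000, (400, 2))
        dup = np.vstack([xy, xy])
        frames = np.r_[np.ones(400, int), np.full(400, 2, int)]
        tab = make_table(dup, frame=frames, n_frames=2)
        res = ns.frc_resolution(tab)
        assert not res.resolved and math.isnan(res.resolution_nm)

    def test_dense_stream_resolution_near_precision_limit(self):
        """Dense 20 nm-precision data resolve to ~3 sigma; the estimate must
        land inside the analytic 2-4 sigma bracket."""
        occ = {k: 0.9 for k in ns.COMPARTMENT_KINDS}
        sp = ns.SceneParams(field_size_um=8, density_vglut1=12,
                            density_vglut2=50, occupancy=occ,
                            clusters_per_occupied=1.0,
                            cluster_diameter_nm=(55.0, 10.0), seed=17)
        scene = ns.generate_scene(sp)
        stream = ns.simulate_localization_events(
            scene, n_frames=4000, mean_events_per_cluster_per_frame=0.1,
            precision_nm=20.0)
        tab = ns.filter_localizations(ns.stream_to_table(stream))
        assert len(tab) > 20000
        res = ns.frc_resolution(tab)
        assert res.resolved
        assert 2 * 20.0 <= res.resolution_nm <= 4 * 20.0

    def test_doubling_error_scales_resolution(self):
        occ = {k: 0.9 for k in ns.COMPARTMENT_KINDS}
        sp = ns.SceneParams(field_size_um=8, density_vglut1=12,
                            density_vglut2=50, occupancy=occ,
                            clusters_per_occupied=1.0,
                            cluster_diameter_nm=(55.0, 10.0), seed=18)
        scene = ns.generate_scene(sp)
        out = {}
        for prec in (20.0, 40.0):
            stream = ns.simulate_localization_events(
                scene, n_frames=4000,
                mean_events_per_cluster_per_frame=0.1, precision_nm=prec)
            tab = ns.filter_localizations(ns.stream_to_table(stream))
            out[prec] = ns.frc_resolution(tab).resolution_nm
        ratio = out[40.0] / out[20.0]
        assert 1.4 <= ratio <= 2.6

    def test_too_few_localizations_raise(self):
        with pytest.raises(ValueError):
            ns.frc_resolution(make_table(np.array([[0.0, 0.0]])))


class TestTableIO:
    def test_csv_round_trip_tolerant_reader(self, tmp_path, rng):
        xy = rng.uniform(0, 1000, (30, 2))
        tab = make_table(xy, frame=rng.integers(1, 50, 30))
        path = tmp_path / "locs.csv"
        tab.to_csv(path)
        back = LocalizationTable.from_csv(path)
        assert np.allclose(back.xy, tab.xy)
        # minimal dialect without quality columns
        tab.rows[["frame", "x_nm", "y_nm", "photons"]].to_csv(
            tmp_path / "min.csv", index=False)
        minimal = LocalizationTable.from_csv(tmp_path / "min.csv")
        assert len(ns.filter_localizations(minimal)) == len(minimal)

    def test_stream_conversion_schema(self, small_scene):
        stream = ns.simulate_localization_events(
            small_scene, n_frames=50,
            mean_events_per_cluster_per_frame=0.05)
        tab = ns.stream_to_table(stream)
        assert list(tab.rows.columns[:6]) == ["frame", "x_nm", "y_nm",
                                              "photons", "signal",
                                              "precision_nm"]
        assert (tab.rows["precision_nm"] > 0).all()
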