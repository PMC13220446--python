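"""Grid segmentation, DBSCAN, hull metrics and Ripley statistics."""

import numpy as np
import pytest
from shapely.geometry import Point, Polygon

from nanoscope import (AnalysisConfig, LocalizationTable, RoiPolygon,
                       analyze_roi, dbscan, hull_metrics, ripley_l,
                       segment_grid)
from nanoscope.io import ConfigurationError

from oracles import (brute_dbscan, exhaustive_hull_area, ripley_k_numeric,
                     same_partition)


def _table(xy):
    xy = np.asarray(xy, float)
    return LocalizationTable.from_arrays(xy[:, 0], xy[:, 1],
                                         np.zeros(len(xy), int))


def _square_roi(size, origin=(0.0, 0.0)):
    x0, y0 = origin
    return RoiPolygon(np.array([[x0, y0], [x0 + size, y0],
                                [x0 + size, y0 + size], [x0, y0 + size]]))


class TestSegmentGrid:
    def test_exact_square_one_subregion(self, rng):
        pts = rng.uniform(0, 3000, size=(50, 2))
        subs = segment_grid(_square_roi(3000.0), _table(pts), 3000.0)
        assert len(subs) == 1
        assert subs[0].n_points == 50

    def test_rectangle_gives_3x2_grid(self, rng):
        roi = RoiPolygon(np.array([[0, 0], [9000, 0], [9000, 6000], [0, 6000]]))
        pts = rng.uniform(0, [9000, 6000], size=(200, 2))
        subs = segment_grid(roi, _table(pts), 3000.0)
        assert len(subs) == 6
        assert sum(s.n_points for s in subs) == 200

    def test_l_shape_matches_containment_oracle(self, rng):
        verts = np.array([[0, 0], [9000, 0], [9000, 3000], [3000, 3000],
                          [3000, 9000], [0, 9000]], float)
        roi = RoiPolygon(verts)
        subs = segment_grid(roi, _table(rng.uniform(0, 9000, (50, 2))), 3000.0)
        kept = {(s.x0, s.y0) for s in subs}
        poly = Polygon(verts)
        expected = set()
        for ix in range(3):
            for iy in range(3):
                x0, y0 = ix * 3000.0, iy * 3000.0
                # dense boundary sampling of the candidate square
                edge = np.linspace(0, 3000, 33)
                pts = ([(x0 + e, y0) for e in edge] + [(x0 + e, y0 + 3000) for e in edge]
                       + [(x0, y0 + e) for e in edge] + [(x0 + 3000, y0 + e) for e in edge])
                if all(poly.covers(Point(p)) for p in pts):
                    expected.add((x0, y0))
        assert kept == expected == {(0.0, 0.0), (3000.0, 0.0), (6000.0, 0.0),
                                    (0.0, 3000.0), (0.0, 6000.0)}

    def test_half_open_point_assignment(self):
        roi = RoiPolygon(np.array([[0, 0], [6000, 0], [6000, 3000], [0, 3000]]))
        t = _table([[3000.0, 100.0], [2999.999, 100.0]])
        subs = segment_grid(roi, t, 3000.0)
        assert subs[0].n_points == 1 and subs[1].n_points == 1

    def test_too_small_roi_warns_empty(self):
        with pytest.warns(UserWarning, match="no grid square"):
            subs = segment_grid(_square_roi(1000.0), _table([[1, 1]]), 3000.0)
        assert subs == []


class TestDbscan:
    def test_five_coincident_points_form_minimal_core(self):
        labels = dbscan(np.zeros((5, 2)), eps=20.0, min_pts=5)
        assert set(labels) == {0}

    def test_four_coincident_points_are_noise(self):
        labels = dbscan(np.zeros((4, 2)), eps=20.0, min_pts=5)
        assert set(labels) == {-1}

    def test_empty_input(self):
        assert dbscan(np.empty((0, 2))).size == 0

    def test_invalid_parameters(self):
        with pytest.raises(ConfigurationError):
            dbscan(np.zeros((3, 2)), eps=-1.0)
        with pytest.raises(ConfigurationError):
            dbscan(np.zeros((3, 2)), min_pts=0)

    @pytest.mark.parametrize("seed", range(6))
    def test_blobs_plus_background_match_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        pts = np.vstack([
            rng.normal(0, 5, (150, 2)) + [1000, 1000],
            rng.normal(0, 5, (150, 2)) + [1500, 1000],
            rng.uniform(0, 3000, (20, 2)),
        ])
        ours = dbscan(pts, 20.0, 5)
        assert same_partition(ours, brute_dbscan(pts, 20.0, 5))

    def test_permutation_invariance_unique_distances(self, rng):
        pts = rng.uniform(0, 200, size=(60, 2))
        labels = dbscan(pts, 25.0, 4)
        perm = rng.permutation(60)
        relabeled = dbscan(pts[perm], 25.0, 4)
        assert same_partition(labels[perm], relabeled)

    def test_increasing_eps_never_increases_noise(self, rng):
        pts = rng.uniform(0, 500, size=(200, 2))
        noise = [np.sum(dbscan(pts, eps, 5) == -1) for eps in (10, 20, 40, 80)]
        assert all(a >= b for a, b in zip(noise, noise[1:]))


class TestHullMetrics:
    def test_triangle(self):
        area, radius, density = hull_metrics([(0, 0), (100, 0), (0, 100)])
        assert area == pytest.approx(5000.0)

    def test_square_with_interior_points(self):
        pts = [(0, 0), (100, 0), (100, 100), (0, 100), (50, 50), (20, 80)]
        area, radius, density = hull_metrics(pts)
        assert area == pytest.approx(10000.0)
        assert radius == pytest.approx(np.sqrt(10000 / np.pi))
        assert density == pytest.approx(6 / 10000.0)

    def test_matches_exhaustive_oracle(self, rng):
        pts = rng.uniform(0, 100, size=(50, 2))
        area, _, _ = hull_metrics(pts)
        assert area == pytest.approx(exhaustive_hull_area(pts), rel=1e-9)

    def test_degenerate_collinear(self):
        area, radius, density = hull_metrics([(0, 0), (10, 10), (20, 20)])
        assert area == 0.0 and radius == 0.0 and np.isnan(density)

    def test_translation_rotation_invariance(self, rng):
        pts = rng.uniform(0, 100, size=(30, 2))
        base, _, _ = hull_metrics(pts)
        th = 0.7
        rot = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        moved, _, _ = hull_metrics(pts @ rot.T + [1234.5, -987.1])
        assert moved == pytest.approx(base, rel=1e-9)

    def test_monotone_under_point_addition(self, rng):
        pts = rng.uniform(0, 100, size=(20, 2))
        a1, _, _ = hull_metrics(pts)
        a2, _, _ = hull_metrics(np.vstack([pts, [[200.0, 200.0]]]))
        assert a2 >= a1


class TestRipley:
    def test_two_point_closed_form(self):
        # both correction circles fully inside -> weight 1; K jumps to A at d
        pts = np.array([[400.0, 500.0], [600.0, 500.0]])
        window = (0.0, 0.0, 1000.0, 1000.0)
        r, L, _ = ripley_l(pts, window, r_max=400.0, n_r=100)
        K = np.pi * L ** 2
        assert np.all(K[r < 200.0 - 1e-9] == 0.0)
        assert np.allclose(K[r >= 200.0], 1e6)

    def test_matches_numeric_integration_oracle(self, rng):
        pts = rng.uniform(0, 1000, size=(40, 2))
        window = (0.0, 0.0, 1000.0, 1000.0)
        r, L, _ = ripley_l(pts, window, r_max=700.0, n_r=35)
        K = np.pi * L ** 2
        K_oracle = ripley_k_numeric(pts, window, r)
        assert np.allclose(K, K_oracle, rtol=5e-3)

    def test_coincident_points_strongly_clustered(self):
        pts = np.zeros((30, 2)) + [1500.0, 1500.0]
        _, L, max_dev = ripley_l(pts, (0, 0, 3000, 3000), 2200.0)
        assert max_dev > 0
        assert L[0] > 10 * (2200.0 / 110)

    def test_fewer_than_two_points_nan(self):
        with pytest.warns(UserWarning):
            _, L, max_dev = ripley_l(np.zeros((1, 2)), (0, 0, 100, 100))
        assert np.isnan(max_dev) and np.isnan(L).all()

    def test_uncorrected_underestimates_at_large_r(self, rng):
        pts = rng.uniform(0, 1000, size=(150, 2))
        w = (0, 0, 1000, 1000)
        _, L_iso, _ = ripley_l(pts, w, 500.0, correction="isotropic")
        _, L_raw, _ = ripley_l(pts, w, 500.0, correction="none")
        assert L_raw[-1] < L_iso[-1]

    def test_translation_correction_close_to_isotropic(self, rng):
        pts = rng.uniform(0, 1000, size=(150, 2))
        w = (0, 0, 1000, 1000)
        r, L_iso, _ = ripley_l(pts, w, 300.0, correction="isotropic")
        _, L_tr, _ = ripley_l(pts, w, 300.0, correction="translation")
        assert np.allclose(L_iso, L_tr, rtol=0.05, atol=2.0)


class TestAnalyzeRoi:
    def test_empty_roi(self):
        with pytest.warns(UserWarning):
            rep = analyze_roi(_table(np.empty((0, 2))), _square_roi(1000.0))
        assert rep.summary["n_subregions"].iloc[0] == 0

    def test_bookkeeping_sums(self, rng):
        pts = np.vstack([rng.normal(0, 8, (60, 2)) + [1000, 1000],
                         rng.uniform(0, 3000, (30, 2))])
        rep = analyze_roi(_table(pts), _square_roi(3000.0))
        sub = rep.subregions.iloc[0]
        n_in_clusters = rep.clusters["n_locs"].sum()
        assert n_in_clusters + sub["n_noise"] == sub["n_points"]
        assert (rep.clusters["n_locs"] >= 5).all()

    def test_csr_background_rarely_forms_clusters(self, rng):
        # 5 molecules / um^2 of pure background: spurious-cluster floor
        rates = []
        for _ in range(20):
            pts = rng.uniform(0, 3000, size=(rng.poisson(45), 2))
            rep = analyze_roi(_table(pts), _square_roi(3000.0), ripley=False)
            rates.append(rep.summary["clusters_per_um2"].iloc[0])
        assert np.mean(rates) < 0.05

    def test_thomas_field_recovery(self):
        from nanoscope.simulate import ThomasSpec, simulate_localizations
        spec = ThomasSpec(window_size=9000.0, n_frames=1, blink_min=1,
                          blink_max=1, precision_nm=1e-6, seed=21)
        table, truth = simulate_localizations(spec)
        rep = analyze_roi(table, truth["window"], ripley=False)
        cpa = rep.summary["clusters_per_um2"].iloc[0]
        lpc = rep.summary["mean_locs_per_cluster"].iloc[0]
        assert cpa == pytest.approx(spec.kappa_per_um2, rel=0.25)
        assert lpc == pytest.approx(spec.mu, rel=0.2)
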