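"""Nano-cluster detection and cluster geometry."""

import numpy as np
import pytest
from shapely.geometry import Polygon
from sklearn.cluster import DBSCAN

from smlmtopo import (Cluster, ClusterCriteria, ClusterPatternSpec, FieldSpec,
                      clusters_per_cell, detect_clusters, fraction_clustered,
                      qc_filter_cells, shoelace_area_centroid,
                      simulate_clustered, simulate_mixture,
                      simulate_homogeneous)
from smlmtopo.clusters import _make_cluster, PRESETS
from oracles import brute_force_density_clusters, monte_carlo_centroid


def _disc(n, center, radius, seed):
    rng = np.random.default_rng(seed)
    r = radius * np.sqrt(rng.uniform(size=n))
    th = rng.uniform(0, 2 * np.pi, n)
    return np.column_stack([center[0] + r * np.cos(th),
                            center[1] + r * np.sin(th)])


class TestDetection:
    def test_single_disc_cluster_fully_recovered(self):
        pts = _disc(50, (500.0, 500.0), 50.0, seed=0)
        crit = ClusterCriteria(200.0, 46)
        found = detect_clusters(pts, crit)
        assert len(found) == 1
        assert set(found[0].members) == set(range(50))
        # brute-force density-connectivity oracle agrees
        oracle = brute_force_density_clusters(pts, 200.0, 46)
        assert {frozenset(found[0].members)} == set(oracle)

    def test_min_points_threshold_boundary(self):
        pts = _disc(45, (500.0, 500.0), 50.0, seed=1)
        assert detect_clusters(pts, ClusterCriteria(200.0, 46)) == []
        assert len(detect_clusters(pts, ClusterCriteria(200.0, 45))) == 1

    def test_empty_input(self):
        assert detect_clusters(np.zeros((0, 2)), ClusterCriteria(200.0, 46)) == []

    @pytest.mark.parametrize("seed", range(5))
    def test_well_separated_clusters_recovered(self, seed):
        spec = ClusterPatternSpec(10, 100, 50.0)
        tab, labels = simulate_clustered(spec, FieldSpec(24_000.0, 24_000.0),
                                         seed=seed)
        found = detect_clusters(tab, ClusterCriteria(200.0, 46))
        assert len(found) == 10
        correct = 0
        for c in found:
            truth = labels[c.members]
            correct += (truth == np.bincount(truth).argmax()).sum()
        assert correct / len(tab) >= 0.95

    def test_max_points_and_max_extent_filters(self):
        pts = _disc(120, (0.0, 0.0), 150.0, seed=2)
        assert detect_clusters(pts, ClusterCriteria(40.0, 4, 100, None)) == []
        assert detect_clusters(pts, ClusterCriteria(40.0, 4, None, 200.0)) == []
        kept = detect_clusters(pts, ClusterCriteria(40.0, 4, None, None))
        assert len(kept) == 1 and kept[0].n_points == 120

    def test_every_reported_cluster_satisfies_criteria(self):
        spec = ClusterPatternSpec(6, 30, 60.0)
        tab, _ = simulate_mixture(spec, 400, FieldSpec(12_000.0, 12_000.0),
                                  seed=3)
        crit = ClusterCriteria(100.0, 10, 80, 400.0)
        for c in detect_clusters(tab, crit):
            assert c.n_points >= crit.min_points
            assert c.n_points <= crit.max_points
            assert c.extent_nm <= crit.max_extent

    def test_rigid_motion_invariance(self):
        spec = ClusterPatternSpec(5, 40, 50.0)
        tab, _ = simulate_clustered(spec, FieldSpec(12_000.0, 12_000.0), seed=4)
        crit = ClusterCriteria(200.0, 30)
        base = detect_clusters(tab, crit)
        th = 0.7
        rot = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        moved = tab.xy @ rot.T + np.array([123.0, -456.0])
        rotated = detect_clusters(moved, crit)
        assert ({frozenset(c.members) for c in base}
                == {frozenset(c.members) for c in rotated})

    def test_core_points_agree_with_sklearn_dbscan(self):
        spec = ClusterPatternSpec(8, 60, 50.0)
        tab, _ = simulate_mixture(spec, 300, FieldSpec(12_000.0, 12_000.0),
                                  seed=5)
        eps, mp = 120.0, 20
        ours = detect_clusters(tab, ClusterCriteria(eps, mp))
        db = DBSCAN(eps=eps, min_samples=mp).fit(tab.xy)
        core = np.zeros(len(tab), bool)
        core[db.core_sample_indices_] = True
        ours_sets = {frozenset(m for m in c.members if core[m]) for c in ours}
        db_sets = {frozenset(np.nonzero(core & (db.labels_ == k))[0])
                   for k in set(db.labels_) if k != -1}
        assert ours_sets == db_sets

    def test_presets_exist(self):
        assert PRESETS["gammaH2AX_fig4"].min_points == 46
        assert PRESETS["gammaH2AX_topology"].min_points == 50
        nuc = PRESETS["nucleosome"]
        assert (nuc.neighborhood_radius, nuc.min_points,
                nuc.max_points, nuc.max_extent) == (40.0, 4, 100, 200.0)


class TestGeometry:
    def test_unit_square_centroid(self):
        area, c = shoelace_area_centroid(
            np.array([[0.0, 0.0], [1.0, 0.0], [1.0, 1.0], [0.0, 1.0]]))
        assert area == pytest.approx(1.0)
        assert c == pytest.approx((0.5, 0.5))

    def test_triangle_centroid_closed_form(self):
        area, c = shoelace_area_centroid(
            np.array([[0.0, 0.0], [3.0, 0.0], [0.0, 3.0]]))
        assert area == pytest.approx(4.5)
        assert c == pytest.approx((1.0, 1.0))

    def test_random_polygon_against_monte_carlo_and_shapely(self):
        rng = np.random.default_rng(7)
        pts = rng.uniform(0, 100, size=(20, 2))
        cl = _make_cluster(np.arange(20), pts)
        poly = Polygon(cl.hull_vertices)
        assert cl.area_um2 * 1e6 == pytest.approx(poly.area, rel=1e-9)
        assert cl.centroid == pytest.approx((poly.centroid.x, poly.centroid.y),
                                            rel=1e-9)
        mc = monte_carlo_centroid(cl.hull_vertices, seed=1)
        assert cl.centroid == pytest.approx(tuple(mc), abs=0.25)

    def test_area_unit_conversion(self):
        sq = np.array([[0.0, 0.0], [1000.0, 0.0], [1000.0, 1000.0],
                       [0.0, 1000.0]])
        cl = _make_cluster(np.arange(4), sq)
        assert cl.area_um2 == pytest.approx(1.0)

    def test_collinear_degenerate(self):
        pts = np.array([[0.0, 0.0], [10.0, 0.0], [20.0, 0.0], [30.0, 0.0]])
        cl = _make_cluster(np.arange(4), pts)
        assert cl.degenerate and cl.area_um2 == 0.0
        assert cl.rms_nm > 0  # RMS over members as fallback

    def test_square_rms_closed_form(self):
        s = 80.0
        sq = np.array([[0.0, 0.0], [s, 0.0], [s, s], [0.0, s]])
        cl = _make_cluster(np.arange(4), sq)
        assert cl.rms_nm == pytest.approx(s / np.sqrt(2))

    def test_regular_polygon_rms_equals_circumradius(self):
        r = 55.0
        th = 2 * np.pi * np.arange(7) / 7
        poly = np.column_stack([r * np.cos(th), r * np.sin(th)])
        cl = _make_cluster(np.arange(7), poly)
        assert cl.rms_nm == pytest.approx(r)

    def test_rms_homogeneity_under_scaling(self):
        rng = np.random.default_rng(8)
        pts = rng.uniform(0, 100, size=(15, 2))
        c1 = _make_cluster(np.arange(15), pts)
        c2 = _make_cluster(np.arange(15), 3.5 * pts)
        assert c2.rms_nm == pytest.approx(3.5 * c1.rms_nm)

    def test_hull_area_converges_to_disc_area(self):
        pts = _disc(10_000, (0.0, 0.0), 100.0, seed=9)
        cl = _make_cluster(np.arange(len(pts)), pts)
        disc_um2 = np.pi * 100.0 ** 2 / 1e6
        assert cl.area_um2 < disc_um2
        assert cl.area_um2 == pytest.approx(disc_um2, rel=0.02)


class TestPerCellSummaries:
    def test_qc_window_boundaries(self):
        def cell(n):
            return simulate_homogeneous(n, FieldSpec(), seed=n)
        tabs = [cell(9_999), cell(10_000), cell(20_000), cell(50_000)]
        kept = qc_filter_cells(tabs, 10_000, 50_000)
        assert [len(t) for t in kept] == [10_000, 20_000, 50_000]
        assert qc_filter_cells([cell(50_001)], 10_000, 50_000) == []

    def test_fraction_clustered_extremes(self):
        pts = _disc(50, (0.0, 0.0), 50.0, seed=10)
        found = detect_clusters(pts, ClusterCriteria(200.0, 46))
        assert fraction_clustered(pts, found) == 100.0
        assert fraction_clustered(pts, []) == 0.0
        with pytest.raises(ValueError):
            fraction_clustered(np.zeros((0, 2)), [])

    def test_fraction_clustered_recovers_mixture_fraction(self):
        spec = ClusterPatternSpec(10, 100, 50.0)
        tab, labels = simulate_mixture(spec, 1000, FieldSpec(24_000.0, 24_000.0),
                                       seed=11)
        found = detect_clusters(tab, ClusterCriteria(100.0, 30))
        truth = 100.0 * (labels >= 0).mean()
        assert fraction_clustered(tab, found) == pytest.approx(truth, abs=5.0)

    def test_clusters_per_cell_summary(self):
        spec = ClusterPatternSpec(20, 60, 50.0)
        tabs = [simulate_clustered(spec, FieldSpec(24_000.0, 24_000.0),
                                   seed=s)[0] for s in range(4)]
        crit = ClusterCriteria(200.0, 46)
        summary = clusters_per_cell(tabs, crit)
        assert summary["median"] == pytest.approx(20, abs=1)
        identical = clusters_per_cell([tabs[0]] * 3, crit)
        assert identical["q3"] - identical["q1"] == 0.0
        empty = clusters_per_cell([simulate_homogeneous(0, FieldSpec(), 0)],
                                  crit)
        assert empty["counts"].tolist() == [0.0]
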