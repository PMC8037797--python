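"""Sphere-growth filtrations, persistence barcodes and barcode statistics."""

import numpy as np
import pytest

from smlmtopo import (Bar, ClusterPatternSpec, FieldSpec, barcode,
                      betti_numbers, build_filtration, endpoint_histogram,
                      persistence_barcode, round_and_prune,
                      simulate_clustered)
from oracles import brute_force_rips_barcode

SQ2 = np.sqrt(2.0)


def _bars_tuple(bc):
    return sorted((b.dimension, round(b.birth, 12),
                   round(b.death, 12) if np.isfinite(b.death) else np.inf)
                  for b in bc.bars)


class TestFiltration:
    def test_two_points_edge_at_half_distance(self):
        f = build_filtration(np.array([[0.0, 0.0], [80.0, 0.0]]))
        assert f.edge_alphas.tolist() == [40.0]

    def test_equilateral_triangle_all_simplices_at_half_side(self):
        s = 60.0
        pts = np.array([[0.0, 0.0], [s, 0.0], [s / 2, s * np.sqrt(3) / 2]])
        f = build_filtration(pts)
        assert np.allclose(f.edge_alphas, s / 2)
        assert np.allclose(f.triangle_alphas, s / 2)

    def test_square_edge_alphas(self):
        s = 2.0
        pts = np.array([[0.0, 0.0], [s, 0.0], [s, s], [0.0, s]])
        f = build_filtration(pts, max_alpha=np.inf)
        assert sorted(np.round(f.edge_alphas, 10)) == pytest.approx(
            [s / 2] * 4 + [s * SQ2 / 2] * 2)

    def test_duplicate_points_merged_with_warning(self):
        pts = np.array([[0.0, 0.0], [0.0, 0.0], [10.0, 0.0]])
        with pytest.warns(UserWarning, match="duplicate"):
            f = build_filtration(pts)
        assert f.n_points == 2


class TestBarcode:
    def test_unit_square_hole(self, unit_square):
        bc = persistence_barcode(build_filtration(unit_square))
        holes = bc.dim(1)
        assert len(holes) == 1
        assert holes[0].birth == pytest.approx(0.5)
        assert holes[0].death == pytest.approx(SQ2 / 2)

    def test_one_essential_component_and_vertex_count(self):
        rng = np.random.default_rng(0)
        pts = rng.uniform(0, 100, size=(12, 2))
        bc = persistence_barcode(build_filtration(pts))
        d0 = bc.dim(0)
        assert len(d0) == 12  # one bar per point
        assert sum(1 for b in d0 if not b.finite) == 1

    def test_isolated_points_all_components_no_holes(self):
        pts = np.array([[0.0, 0.0], [1000.0, 0.0], [0.0, 1000.0]])
        f = build_filtration(pts)
        assert betti_numbers(f, 100.0) == (3, 0)

    def test_single_component_beyond_half_max_distance(self):
        rng = np.random.default_rng(1)
        pts = rng.uniform(0, 200, size=(20, 2))
        from scipy.spatial.distance import pdist
        f = build_filtration(pts)
        b0, _ = betti_numbers(f, pdist(pts).max() / 2 + 1e-9)
        assert b0 == 1

    def test_b0_non_increasing_in_alpha(self):
        rng = np.random.default_rng(2)
        pts = rng.uniform(0, 100, size=(15, 2))
        f = build_filtration(pts)
        b0s = [betti_numbers(f, a)[0] for a in np.linspace(0, 120, 25)]
        assert all(x >= y for x, y in zip(b0s, b0s[1:]))
        assert b0s[0] == 15

    @pytest.mark.parametrize("n,seed", [(4, 0), (5, 1), (6, 2), (7, 3),
                                        (8, 4), (8, 5), (8, 6)])
    def test_matches_brute_force_reduction(self, n, seed):
        pts = np.random.default_rng(seed).uniform(0, 100, size=(n, 2))
        ours = _bars_tuple(persistence_barcode(build_filtration(pts)))
        oracle = [(d, round(b, 12), round(x, 12) if np.isfinite(x) else np.inf)
                  for d, b, x in brute_force_rips_barcode(pts)]
        assert ours == sorted(oracle)

    def test_unit_square_matches_oracle(self, unit_square):
        ours = _bars_tuple(persistence_barcode(build_filtration(unit_square)))
        oracle = [(d, round(b, 12), round(x, 12) if np.isfinite(x) else np.inf)
                  for d, b, x in brute_force_rips_barcode(unit_square)]
        assert ours == sorted(oracle)
        assert (1, 0.5, round(SQ2 / 2, 12)) in ours

    def test_rigid_motion_invariance(self):
        rng = np.random.default_rng(3)
        pts = rng.uniform(0, 100, size=(10, 2))
        th = 1.1
        rot = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        moved = pts @ rot.T + np.array([5.0, -30.0])
        a = _bars_tuple(persistence_barcode(build_filtration(pts)))
        b = _bars_tuple(persistence_barcode(build_filtration(moved)))
        assert a == pytest.approx(b)

    def test_uniform_scaling_scales_endpoints(self):
        rng = np.random.default_rng(4)
        pts = rng.uniform(0, 100, size=(9, 2))
        k = 2.75
        a = persistence_barcode(build_filtration(pts))
        b = persistence_barcode(build_filtration(k * pts))
        for ba, bb in zip(a.bars, b.bars):
            assert bb.birth == pytest.approx(k * ba.birth)
            if ba.finite:
                assert bb.death == pytest.approx(k * ba.death)

    def test_alpha_backend_square_and_oracle_deaths(self, unit_square):
        bc = barcode(unit_square, backend="alpha")
        holes = bc.dim(1)
        assert len(holes) == 1
        assert holes[0].birth == pytest.approx(0.5)
        assert holes[0].death == pytest.approx(SQ2 / 2)
        d0 = bc.dim(0)
        assert len(d0) == 4 and sum(1 for b in d0 if not b.finite) == 1

    def test_subsample_is_seeded_and_reduces_size(self):
        rng = np.random.default_rng(5)
        pts = rng.uniform(0, 500, size=(60, 2))
        a = barcode(pts, subsample=20, seed=9)
        b = barcode(pts, subsample=20, seed=9)
        assert _bars_tuple(a) == _bars_tuple(b)
        assert a.n_points == 20


class TestRoundAndPrune:
    def test_short_bar_pruned_long_bar_kept(self):
        bc_in = barcode(np.array([[0.0, 0.0], [2.0, 0.0]]))  # death 1 nm
        out = round_and_prune(bc_in, decimals=2, unit="um")
        # 1 nm = 0.001 um rounds to 0.00 == birth: pruned
        assert all(not b.finite for b in out.bars)
        kept = round_and_prune(
            barcode(np.array([[0.0, 0.0], [200.0, 0.0]])), 2, "um")
        deaths = [b.death for b in kept.bars if b.finite]
        assert deaths == [0.1]

    def test_pruning_never_increases_bar_count(self):
        rng = np.random.default_rng(6)
        pts = rng.uniform(0, 300, size=(15, 2))
        bc = barcode(pts)
        out = round_and_prune(bc)
        assert len(out.bars) <= len(bc.bars)
        assert out.unit == "um"

    def test_identity_in_nm_at_high_decimals(self):
        bc = barcode(np.array([[0.0, 0.0], [123.456, 0.0]]))
        out = round_and_prune(bc, decimals=6, unit="nm")
        assert [b.death for b in out.bars if b.finite] == [61.728]


class TestEndpointHistogram:
    def _nucleus_barcodes(self, radius_scale, n=3):
        bcs = []
        for seed in range(n):
            spec = ClusterPatternSpec(12, 25, 120.0 * radius_scale)
            tab, _ = simulate_clustered(spec, FieldSpec(8000.0, 8000.0),
                                        seed=seed)
            bcs.append(barcode(tab, backend="alpha"))
        return bcs

    def test_frequencies_sum_to_one_per_dimension(self):
        bcs = self._nucleus_barcodes(1.0)
        edges = np.arange(0.0, 2000.0, 50.0)
        eh = endpoint_histogram(bcs, edges)
        assert eh.freq_dim0.sum() == pytest.approx(1.0, abs=1e-9)
        assert eh.freq_dim1.sum() == pytest.approx(1.0, abs=1e-9)

    def test_single_nucleus_average_is_itself(self):
        bcs = self._nucleus_barcodes(1.0, n=1)
        edges = np.arange(0.0, 2000.0, 50.0)
        eh1 = endpoint_histogram(bcs, edges)
        deaths = bcs[0].finite_deaths(1)
        expect, _ = np.histogram(deaths, bins=edges)
        np.testing.assert_allclose(eh1.freq_dim1, expect / expect.sum())

    def test_decondensation_shifts_hole_endpoints_up(self):
        # inflating domain radii 1.5x moves dimension-1 endpoint mass to
        # larger alpha (looser chromatin -> larger holes)
        edges = np.arange(0.0, 3000.0, 50.0)
        ctrl = endpoint_histogram(self._nucleus_barcodes(1.0), edges)
        decon = endpoint_histogram(self._nucleus_barcodes(1.5), edges)
        centers = 0.5 * (edges[:-1] + edges[1:])
        assert (decon.freq_dim1 @ centers) > (ctrl.freq_dim1 @ centers)

    def test_empty_dimension_skipped(self):
        bc2 = barcode(np.array([[0.0, 0.0], [50.0, 0.0]]))  # no holes
        eh = endpoint_histogram([bc2], np.arange(0.0, 100.0, 10.0))
        assert eh.skipped[1] == 1
        assert eh.freq_dim1.sum() == 0.0


class TestBarValidation:
    def test_bar_invariants(self):
        with pytest.raises(ValueError):
            Bar(2, 0.0, 1.0)
        with pytest.raises(ValueError):
            Bar(0, 1.0, 0.5)
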