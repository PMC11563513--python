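"""Phenotype panel: densities, FAZ, tortuosity, Murray KS, symmetry."""

import math

import numpy as np
import pytest

from octava import TreeSpec, compute_all, generate_tree
from octava.graph import Bifurcation
from octava.phenotypes import (
    branching_points,
    detect_faz,
    make_region_masks,
    mean_bifurcation_distance,
    mean_radius,
    mean_symmetry_ratio,
    mean_tortuosity,
    murray_ks_score,
    vessel_density,
)
from octava.segmentation import BinaryVesselMask
from tests.conftest import straight_tube_mask


def ks_oracle(x, y):
    """Brute-force two-sample KS: sup over pooled points of |F1 - F2|."""
    x, y = np.sort(x), np.sort(y)
    pooled = np.concatenate([x, y])
    f1 = np.searchsorted(x, pooled, side="right") / len(x)
    f2 = np.searchsorted(y, pooled, side="right") / len(y)
    return np.max(np.abs(f1 - f2))


class TestRegions:
    def test_foveal_circle_pixel_count(self):
        rm = make_region_masks((512, 512), 3000.0 / 512, 1.0, 3.0)
        r_px = 0.5 * 1000 / (3000.0 / 512)
        assert r_px == pytest.approx(85.33, abs=0.01)
        assert rm.foveal_circle.sum() == pytest.approx(math.pi * r_px**2, rel=0.01)

    def test_regions_disjoint(self):
        rm = make_region_masks((256, 256), 3000.0 / 256)
        assert not (rm.foveal_circle & rm.parafoveal_ring).any()

    def test_ring_touching_edge_ok(self):
        rm = make_region_masks((128, 128), 3000.0 / 128, 1.0, 3.0)
        assert rm.parafoveal_ring.any()

    def test_oversized_geometry_rejected(self):
        with pytest.raises(ValueError):
            make_region_masks((128, 128), 3000.0 / 128, 1.0, 4.0)


class TestVesselDensity:
    def test_full_and_empty_and_half(self):
        region = np.zeros((20, 20), bool)
        region[5:15, 5:15] = True
        full = BinaryVesselMask(mask=np.ones((20, 20), bool), scale_um_per_px=1.0)
        empty = BinaryVesselMask(mask=np.zeros((20, 20), bool), scale_um_per_px=1.0)
        half_arr = np.zeros((20, 20), bool)
        half_arr[5:10, 5:15] = True
        half = BinaryVesselMask(mask=half_arr, scale_um_per_px=1.0)
        assert vessel_density(full, region) == 1.0
        assert vessel_density(empty, region) == 0.0
        assert vessel_density(half, region) == 0.5

    def test_empty_region_raises(self):
        m = BinaryVesselMask(mask=np.ones((8, 8), bool), scale_um_per_px=1.0)
        with pytest.raises(ValueError):
            vessel_density(m, np.zeros((8, 8), bool))

    def test_density_partition_additivity(self):
        rng = np.random.default_rng(0)
        m = BinaryVesselMask(mask=rng.random((64, 64)) > 0.6, scale_um_per_px=1.0)
        top = np.zeros((64, 64), bool)
        top[:32] = True
        vd_top = vessel_density(m, top)
        vd_bot = vessel_density(m, ~top)
        total = vessel_density(m, np.ones((64, 64), bool))
        assert 0.5 * vd_top + 0.5 * vd_bot == pytest.approx(total, abs=1e-12)


class TestFAZ:
    def test_ring_bounded_pocket(self, scene_mask):
        mask, truth = scene_mask
        rm = make_region_masks(mask.mask.shape, mask.scale_um_per_px)
        area, comp = detect_faz(mask, rm.central_region)
        assert area == pytest.approx(math.pi * 0.3**2, rel=0.05)
        assert comp.any()

    def test_all_false_mask_returns_whole_background(self):
        m = BinaryVesselMask(mask=np.zeros((128, 128), bool), scale_um_per_px=10.0)
        central = np.zeros((128, 128), bool)
        central[54:74, 54:74] = True
        area, comp = detect_faz(m, central)
        assert comp.sum() == 128 * 128

    def test_largest_pocket_wins(self):
        arr = np.ones((64, 64), bool)
        arr[10:20, 10:20] = False  # 100-px pocket
        arr[30:50, 30:50] = False  # 400-px pocket
        m = BinaryVesselMask(mask=arr, scale_um_per_px=1.0)
        central = np.ones((64, 64), bool)
        _, comp = detect_faz(m, central)
        assert comp.sum() == 400

    def test_no_pocket_raises(self):
        m = BinaryVesselMask(mask=np.ones((32, 32), bool), scale_um_per_px=1.0)
        with pytest.raises(ValueError):
            detect_faz(m, np.ones((32, 32), bool))


class TestTortuosity:
    def _graph(self, mask):
        from octava.graph import build_graph, prune_spurs, radius_from_distance, skeletonize

        return prune_spurs(build_graph(radius_from_distance(mask, skeletonize(mask))), 20.0)

    def test_straight_segment_unity(self):
        # rasterized tube: tiny end-cap jogs keep this just above 1
        g = self._graph(straight_tube_mask(6))
        assert mean_tortuosity(g) == pytest.approx(1.0, abs=2e-3)

    def test_semicircle_matches_pi_over_two(self):
        from octava.synth.raster import _paint_polyline

        mask = np.zeros((512, 512), bool)
        t = np.linspace(0, np.pi, 600)
        _paint_polyline(mask, 400 - 150 * np.sin(t), 255.5 + 150 * np.cos(t), 4.0)
        g = self._graph(BinaryVesselMask(mask=mask, scale_um_per_px=5.86))
        assert mean_tortuosity(g) == pytest.approx(np.pi / 2, rel=0.02)

    def test_sinusoid_matches_quadrature(self):
        from scipy.integrate import quad

        from octava.synth.raster import _paint_polyline

        lam, amp = 400.0, 20.0
        x = np.linspace(0, lam, 1200)
        y = amp * np.sin(2 * np.pi * x / lam)
        mask = np.zeros((200, 512), bool)
        _paint_polyline(mask, 100 + y, 50 + x, 4.0)
        g = self._graph(BinaryVesselMask(mask=mask, scale_um_per_px=1.0))
        k = 2 * np.pi / lam
        arc, _ = quad(lambda t: math.sqrt(1 + (amp * k * math.cos(k * t)) ** 2), 0, lam)
        assert mean_tortuosity(g) == pytest.approx(arc / lam, rel=0.02)

    def test_no_eligible_segments_raises(self):
        from octava.graph import VesselGraph

        with pytest.raises(ValueError):
            mean_tortuosity(VesselGraph(nodes={}, segments=[], scale_um_per_px=1.0))


class TestBranchingAndBifurcation:
    def test_single_segment_no_branching(self):
        from octava.graph import build_graph, radius_from_distance, skeletonize

        m = straight_tube_mask(6)
        g = build_graph(radius_from_distance(m, skeletonize(m)))
        assert branching_points(g) == 0
        assert mean_bifurcation_distance(g) is None

    def test_y_fixture_one_branching_point(self, y_mask):
        from octava.graph import build_graph, prune_spurs, radius_from_distance, skeletonize

        g = prune_spurs(build_graph(radius_from_distance(y_mask, skeletonize(y_mask))), 15.0)
        assert branching_points(g) == 1
        assert mean_bifurcation_distance(g) is None  # no junction-junction segment

    def test_bifurcation_distance_on_tree(self):
        from octava import clean_mask, rasterize_tree
        from octava.graph import build_graph, prune_spurs, radius_from_distance, skeletonize

        tree = generate_tree(TreeSpec(seed=1, branch_levels=4))
        arr, truth = rasterize_tree(tree, 512)
        m = clean_mask(BinaryVesselMask(mask=arr, scale_um_per_px=truth.scale_um_per_px), 30, 20)
        g = prune_spurs(build_graph(radius_from_distance(m, skeletonize(m))), 10.0)
        expected = truth.mean_internal_branch_length_um()
        got = mean_bifurcation_distance(g)
        assert got == pytest.approx(expected, abs=2 * truth.scale_um_per_px + 0.03 * expected)


class TestMurrayKS:
    def test_exact_murray_tree_scores_zero(self):
        tree = generate_tree(TreeSpec(seed=0, murray_exponent=3.0))
        bifs = [Bifurcation(0, b.parent_radius_um, b.daughter_radii_um, 0) for b in tree.truth.bifurcations]
        assert murray_ks_score(bifs) == 0.0

    def test_disjoint_singletons_score_one(self):
        bifs = [Bifurcation(0, 1.0, (1.0, 1.0), 0)] * 5
        # parents {1}, daughter sums {2}: disjoint supports -> D = 1
        assert murray_ks_score(bifs) == 1.0

    def test_matches_bruteforce_oracle_on_random_pairs(self):
        from scipy.stats import ks_2samp

        rng = np.random.default_rng(42)
        for _ in range(200):
            n1, n2 = rng.integers(3, 40, 2)
            x, y = rng.random(n1), rng.random(n2) * rng.uniform(0.5, 2)
            assert ks_2samp(x, y, method="asymp").statistic == pytest.approx(
                ks_oracle(x, y), abs=1e-12
            )

    def test_too_few_bifurcations_missing(self):
        bifs = [Bifurcation(0, 1.0, (0.8, 0.8), 0)] * 3
        assert murray_ks_score(bifs, min_bifurcations=5) is None


class TestSymmetryAndRadius:
    def test_symmetric_bifurcations_score_one(self):
        bifs = [Bifurcation(0, 10.0, (7.9, 7.9), 0)] * 4
        assert mean_symmetry_ratio(bifs) == pytest.approx(1.0)

    def test_asymmetric_pair(self):
        bifs = [Bifurcation(0, 20.0, (10.0, 20.0), 0)]
        assert mean_symmetry_ratio(bifs) == pytest.approx(0.5)

    def test_no_bifurcations_missing(self):
        assert mean_symmetry_ratio([]) is None

    def test_generator_symmetry_recovered(self, scene_mask):
        mask, _ = scene_mask
        rec = compute_all(mask)
        assert rec.symmetry_ratio == pytest.approx(0.8, abs=0.05)

    def test_uniform_tube_radius(self):
        from octava.graph import build_graph, radius_from_distance, skeletonize

        m = straight_tube_mask(16)  # half-width 8 px
        g = build_graph(radius_from_distance(m, skeletonize(m)))
        assert mean_radius(g) == pytest.approx(8 * 5.86, abs=0.6 * 5.86)

    def test_empty_graph_missing(self):
        from octava.graph import VesselGraph

        assert mean_radius(VesselGraph(nodes={}, segments=[], scale_um_per_px=1.0)) is None


class TestComputeAll:
    def test_deterministic(self, scene_mask):
        mask, _ = scene_mask
        r1 = compute_all(mask)
        r2 = compute_all(mask)
        assert r1.to_dict() == r2.to_dict()

    def test_empty_mask_gives_nulls_not_zeros(self):
        m = BinaryVesselMask(mask=np.zeros((256, 256), bool), scale_um_per_px=3000.0 / 256)
        rec = compute_all(m)
        assert rec.parafoveal_vd == 0.0 and rec.foveal_vd == 0.0
        assert rec.branching_points is None
        assert rec.ks_score is None
        assert rec.tortuosity_large is None

    def test_panel_recovery_on_clean_scene(self, scene_mask):
        mask, truth = scene_mask
        rec = compute_all(mask)
        assert rec.faz_area_mm2 == pytest.approx(math.pi * 0.3**2, rel=0.05)
        assert rec.ks_score is not None and rec.ks_score <= 0.25
        assert 1.0 <= rec.tortuosity_small < 1.3
        assert rec.branching_points >= truth.n_bifurcations  # ring junctions add a few
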