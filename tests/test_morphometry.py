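"""Skeleton graph construction, mesh detection and the feature vector."""

import math

import numpy as np
import pytest

from valvemorph import morphometry as mm
from valvemorph import synthgen
from valvemorph.imageprep import binarize, skeletonize
from valvemorph.morphometry import (
    FEATURE_NAMES,
    ValveAnnotation,
    build_skeleton_graph,
    compute_features,
    detect_meshes,
    estimate_valve_diameter,
)

from conftest import as_mask, as_skeleton


class TestSkeletonGraph:
    def test_y_shape(self, y_skeleton):
        g = build_skeleton_graph(y_skeleton)
        assert g.n_junctions == 1
        assert g.n_extremities == 3
        kinds = [e.kind for e in g.edges]
        assert kinds.count("branch") == 3
        assert kinds.count("segment") == 0
        assert detect_meshes(y_skeleton).n_meshes == 0
        # three orthogonal 10-step arms
        assert sum(e.length_px for e in g.edges) == pytest.approx(30.0)

    def test_straight_line_is_isolated_element(self, line_skeleton):
        g = build_skeleton_graph(line_skeleton)
        assert g.n_junctions == 0
        assert g.n_extremities == 2
        assert len(g.edges) == 1
        assert g.edges[0].kind == "isolated"
        assert g.n_components == 1
        assert g.total_length_px() == pytest.approx(49.0)

    def test_lattice_cyclomatic_number(self, lattice_skeleton):
        g = build_skeleton_graph(lattice_skeleton)
        # 12 side-midpoint/interior crossings are junctions; the 4 lattice
        # corners have degree 2 and are absorbed into edge polylines
        assert g.n_junctions == 12
        assert g.n_extremities == 0
        assert g.cyclomatic_number() == 9
        assert detect_meshes(lattice_skeleton).n_meshes == 9

    def test_diagonal_steps_counted_sqrt2(self):
        m = np.zeros((20, 20), bool)
        for i in range(10):
            m[5 + i, 5 + i] = True
        g = build_skeleton_graph(as_skeleton(m))
        assert g.total_length_px() == pytest.approx(9 * math.sqrt(2))

    def test_deterministic_ordering(self, lattice_skeleton):
        g1 = build_skeleton_graph(lattice_skeleton)
        g2 = build_skeleton_graph(lattice_skeleton)
        assert [v.anchor for v in g1.vertices] == [v.anchor for v in g2.vertices]
        assert [e.polyline for e in g1.edges] == [e.polyline for e in g2.edges]


class TestMeshes:
    def test_square_outline_single_mesh(self, square_outline_skeleton):
        ms = detect_meshes(square_outline_skeleton)
        assert ms.n_meshes == 1
        assert ms.areas_px2 == [18 * 18]

    def test_theta_two_meshes(self, theta_skeleton):
        assert detect_meshes(theta_skeleton).n_meshes == 2

    def test_tree_has_no_mesh(self, y_skeleton):
        assert detect_meshes(y_skeleton).n_meshes == 0


class TestEulerOracle:
    """Flood-fill mesh count must equal E - V + C of the graph."""

    @pytest.mark.parametrize("supply,seed", [(0.0, 1), (0.5, 2), (1.0, 3)])
    def test_generated_patterns(self, supply, seed):
        spec = synthgen.PatternSpec(supply=supply, radius_px=80, seed=seed)
        img, _ = synthgen.generate_valve_pattern(spec)
        sk = skeletonize(binarize(img), prune_px=4)
        g = build_skeleton_graph(sk)
        assert detect_meshes(sk).n_meshes == g.cyclomatic_number()

    def test_rotation_invariance(self):
        img, _ = synthgen.generate_valve_pattern(
            synthgen.PatternSpec(supply=0.7, radius_px=80, seed=11)
        )
        sk = skeletonize(binarize(img), prune_px=4)
        base = (build_skeleton_graph(sk).n_junctions, detect_meshes(sk).n_meshes)
        for k in (1, 2, 3):
            rot = as_skeleton(np.rot90(sk.pixels, k))
            assert (
                build_skeleton_graph(rot).n_junctions,
                detect_meshes(rot).n_meshes,
            ) == base


class TestValveDiameter:
    def test_disc_identity(self):
        yy, xx = np.ogrid[:250, :250]
        disc = (yy - 125) ** 2 + (xx - 125) ** 2 <= 100**2
        d = estimate_valve_diameter(as_mask(disc))
        assert d == pytest.approx(200.0, abs=2.0)

    def test_square_equivalent_diameter(self):
        m = np.zeros((80, 80), bool)
        m[10:60, 10:60] = True  # side 50
        d = estimate_valve_diameter(as_mask(m))
        assert d == pytest.approx(50 * math.sqrt(4 / math.pi), rel=0.03)

    def test_single_pixel(self):
        m = np.zeros((5, 5), bool)
        m[2, 2] = True
        assert estimate_valve_diameter(as_mask(m)) == pytest.approx(math.sqrt(4 / math.pi))

    def test_empty_mask_raises(self):
        with pytest.raises(ValueError):
            estimate_valve_diameter(as_mask(np.zeros((5, 5))))


class TestFeatureVector:
    def test_y_shape_features(self, y_skeleton):
        g = build_skeleton_graph(y_skeleton)
        fv = compute_features(g, detect_meshes(y_skeleton))
        assert fv.total_branch_length == pytest.approx(30.0)
        assert fv.n_meshes == 0
        assert fv.total_mesh_area == 0.0
        assert fv.mean_mesh_area == 0.0
        assert fv.n_nodes == fv.n_junctions + fv.n_extremities == 4

    def test_lattice_mesh_area(self, lattice_skeleton):
        g = build_skeleton_graph(lattice_skeleton)
        fv = compute_features(g, detect_meshes(lattice_skeleton))
        assert fv.n_meshes == 9
        assert fv.total_mesh_area == pytest.approx(9 * 36.0)

    def test_zero_rimoportulae_rate(self, y_skeleton):
        g = build_skeleton_graph(y_skeleton)
        fv = compute_features(
            g, detect_meshes(y_skeleton), ValveAnnotation(0, valve_area_um2=100.0)
        )
        assert fv.rimoportulae_per_area == 0.0

    def test_length_conservation_and_schema(self):
        img, _ = synthgen.generate_valve_pattern(
            synthgen.PatternSpec(supply=0.6, radius_px=80, seed=5)
        )
        sk = skeletonize(binarize(img), prune_px=4)
        g = build_skeleton_graph(sk)
        fv = compute_features(g, detect_meshes(sk), valve_mask=binarize(img))
        assert fv.total_length == pytest.approx(
            fv.total_segment_length + fv.total_branch_length + fv.total_isolated_length
        )
        s = fv.to_series()
        assert list(s.index) == FEATURE_NAMES
        counts = [
            "n_extremities", "n_nodes", "n_junctions", "n_master_junctions",
            "n_segments", "n_master_segments", "n_branches", "n_isolated", "n_meshes",
        ]
        for c in counts:
            assert s[c] >= 0 and float(s[c]).is_integer()

    def test_pixel_size_scaling(self, theta_skeleton):
        sk2 = as_skeleton(theta_skeleton.pixels, pixel_size_um=0.5)
        fv1 = compute_features(
            build_skeleton_graph(theta_skeleton), detect_meshes(theta_skeleton)
        )
        fv2 = compute_features(build_skeleton_graph(sk2), detect_meshes(sk2))
        assert fv2.total_length == pytest.approx(0.5 * fv1.total_length)
        assert fv2.total_mesh_area == pytest.approx(0.25 * fv1.total_mesh_area)
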