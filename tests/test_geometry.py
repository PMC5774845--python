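import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial import cKDTree

from lingualsonar import geometry as geo


class TestBuildSimplifiedHead:
    def test_bounding_box_matches_requested_dimensions(self, head):
        span = head.vertices.max(axis=0) - head.vertices.min(axis=0)
        np.testing.assert_allclose(span, [40.0, 25.0, 25.0], atol=1e-9)

    def test_watertight_and_outward_oriented(self, head):
        head.check_watertight()

    def test_deterministic_construction(self, head):
        again = geo.build_simplified_head(40.0, 25.0, 25.0, edge_length=1.0)
        assert np.array_equal(head.vertices, again.vertices)
        assert np.array_equal(head.triangles, again.triangles)

    def test_ear_removal_is_a_local_edit(self, head):
        no_ears = geo.build_simplified_head(40.0, 25.0, 25.0,
                                            edge_length=1.0, ears=False)
        moved = np.linalg.norm(head.vertices - no_ears.vertices, axis=1)
        frac = np.mean(moved > 0)
        assert 0.0 < frac < 0.35          # only the ear patches change
        assert no_ears.provenance == "variant"

    def test_mouth_line_node_density(self):
        fine = geo.build_simplified_head(edge_length=0.5)
        per_side = np.sum(fine.mouth_side == "L")
        assert per_side >= 8
        # seam arc length per side is ~15 mm at 0.5 mm edges
        assert per_side == np.sum(fine.mouth_side == "R")

    def test_invalid_dimensions_rejected(self):
        with pytest.raises(ValueError):
            geo.build_simplified_head(0.0, 25.0, 25.0)


class TestPlaceElements:
    def test_left_side_elements_left_of_midline(self, head):
        arr = geo.place_elements(head, "left", "discrete", n=4)
        assert arr.n_elements == 4
        assert np.all(arr.positions[:, 1] > 0)

    def test_both_sides_mirror_symmetric(self, head):
        arr = geo.place_elements(head, "both", "discrete", n=4)
        assert arr.n_elements == 8
        mirrored = arr.positions * [1.0, -1.0, 1.0]
        a = sorted(map(tuple, np.round(arr.positions, 9)))
        b = sorted(map(tuple, np.round(mirrored, 9)))
        assert a == b

    def test_continuous_spacing_near_target(self):
        fine = geo.build_simplified_head(edge_length=0.5)
        arr = geo.place_elements(fine, "left", "continuous", spacing=0.5)
        gaps = np.linalg.norm(np.diff(arr.positions, axis=0), axis=1)
        assert np.all(gaps >= 0.25) and np.all(gaps <= 0.75)

    def test_rostral_ordering(self, head):
        arr = geo.place_elements(head, "left", "discrete", n=5)
        assert np.all(np.diff(arr.positions[:, 0]) < 0)

    def test_too_many_elements_rejected(self, head):
        with pytest.raises(ValueError):
            geo.place_elements(head, "left", "discrete", n=10000)


class TestElementRanges:
    def test_pythagorean_distance(self):
        arr = geo.ArraySpec(np.array([[3.0, 4.0, 0.0]]), "left", "discrete")
        t = geo.TonguePosition(np.zeros(3))
        assert geo.element_ranges(t, arr).r_n[0] == pytest.approx(5.0)

    def test_symmetric_elements_equidistant_from_midline_tongue(self, head):
        arr = geo.place_elements(head, "both", "discrete", n=3)
        t = geo.TonguePosition(np.array([8.0, 0.0, -4.0]))
        r = geo.element_ranges(t, arr).r_n
        assert np.allclose(sorted(r[:3]), sorted(r[3:]))

    def test_coincident_tongue_rejected(self, head):
        arr = geo.place_elements(head, "left", "discrete", n=2)
        t = geo.TonguePosition(arr.positions[0])
        with pytest.raises(ValueError):
            geo.element_ranges(t, arr)

    def test_lateral_tongue_shift_changes_ranges_monotonically(self, head):
        arr = geo.place_elements(head, "left", "discrete", n=6)
        t0 = geo.default_tongue(head, lateral=0.0)
        t1 = geo.default_tongue(head, lateral=6.0)
        d = (geo.element_ranges(t1, arr).r_n
             - geo.element_ranges(t0, arr).r_n)
        # moving the tongue toward the (left) array shortens every range
        assert np.all(d < 0)

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(angle=st.floats(-np.pi, np.pi),
           shift=st.lists(st.floats(-50, 50), min_size=3, max_size=3))
    def test_ranges_invariant_under_rigid_transform(self, head, angle,
                                                    shift):
        arr = geo.place_elements(head, "left", "discrete", n=4)
        t = geo.default_tongue(head)
        base = geo.element_ranges(t, arr).r_n
        c, s = np.cos(angle), np.sin(angle)
        rot = np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])
        # side tags are frame-dependent; "both" carries no side constraint
        arr2 = geo.ArraySpec(arr.positions @ rot.T + shift, "both",
                             "discrete")
        t2 = geo.TonguePosition(rot @ t.location + shift)
        np.testing.assert_allclose(geo.element_ranges(t2, arr2).r_n, base,
                                   rtol=0, atol=1e-9)

    def test_bilateral_mirror_symmetry(self, head):
        left = geo.place_elements(head, "left", "discrete", n=5)
        right = geo.place_elements(head, "right", "discrete", n=5)
        t_l = geo.default_tongue(head, lateral=2.0)
        t_r = geo.default_tongue(head, lateral=-2.0)
        r_l = geo.element_ranges(t_l, left).r_n
        r_r = geo.element_ranges(t_r, right).r_n
        np.testing.assert_allclose(np.sort(r_l), np.sort(r_r), atol=1e-9)


class TestMeshIO:
    @pytest.mark.parametrize("ext", [".obj", ".stl"])
    def test_round_trip_preserves_geometry(self, head, tmp_path, ext):
        path = tmp_path / f"head{ext}"
        geo.write_mesh(head, path)
        back = geo.read_mesh(path)
        tree = cKDTree(back.vertices)
        dist, _ = tree.query(head.vertices)
        assert dist.max() < 1e-4
        assert len(back.mouth_line) == len(head.mouth_line)
        np.testing.assert_allclose(back.mouth_points, head.mouth_points,
                                   atol=1e-4)
        back.check_watertight()

    def test_unknown_extension_rejected(self, head, tmp_path):
        with pytest.raises(ValueError):
            geo.write_mesh(head, tmp_path / "head.ply")

    def test_flipped_normals_reoriented(self, head, tmp_path):
        path = tmp_path / "flipped.obj"
        geo.write_mesh(head, path)
        # flip winding in the OBJ by reversing each face line
        flipped = geo.HeadMesh(head.vertices, head.triangles[:, ::-1],
                               head.mouth_line, head.mouth_side)
        geo.write_mesh(flipped, path)
        with pytest.warns(UserWarning, match="flipped"):
            back = geo.read_mesh(path)
        assert back.as_trimesh().volume > 0


class TestTongue:
    def test_default_tongue_inside_cavity(self, head):
        t = geo.default_tongue(head)
        lo, hi = geo.mouth_cavity_bounds(head)
        assert np.all(t.location >= lo) and np.all(t.location <= hi)

    def test_tongue_outside_cavity_rejected(self, head):
        with pytest.raises(ValueError):
            geo.validate_tongue(
                geo.TonguePosition(np.array([0.0, 0.0, 50.0])), head)
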