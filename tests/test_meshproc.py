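"""Mesh preprocessing: centerline, diameter, crops, repair, remeshing."""

import math
import warnings

import numpy as np
import pytest
import trimesh
from scipy.spatial import cKDTree

from aneupoint import meshproc as mp
from aneupoint import synthgeom as sg


@pytest.fixture(scope="module")
def fused_with_centerline(fused_model):
    cl = mp.fit_centerline(fused_model)
    neck = mp.detect_neck(fused_model, cl)
    return fused_model, cl, neck


@pytest.fixture(scope="module")
def cut1_result(fused_with_centerline):
    mesh, cl, neck = fused_with_centerline
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        d = mp.measure_parent_diameter(mesh, cl, neck.s_lo - 1.0)
    cut = mp.CutSpec(neck_point=0, cut_distance=d,
                     neck_span=(neck.s_lo, neck.s_hi))
    return mp.cut1_crop(mesh, cl, cut), d


class TestCenterline:
    def test_straight_tube_axis_recovered(self, straight_vessel):
        cl = mp.fit_centerline(straight_vessel)
        dev = np.linalg.norm(cl.points[:, 1:], axis=1)
        assert np.sqrt((dev ** 2).mean()) < 0.1

    def test_curved_tube_matches_analytic_arc(self, curved_vessel):
        cl = mp.fit_centerline(curved_vessel)
        true = sg.vessel_centerline(sg.ShapeParams(vessel_curvature=0.03),
                                    n=3000)
        d, _ = cKDTree(true).query(cl.points)
        assert np.sqrt((d ** 2).mean()) < 0.05 * 1.5

    def test_radii_match_tube_radius_away_from_ends(self, straight_vessel):
        cl = mp.fit_centerline(straight_vessel)
        inner = cl.radii[2:-2]
        assert np.abs(inner - 1.5).max() / 1.5 < 0.05

    def test_polyline_lies_inside_mesh(self, fused_with_centerline):
        mesh, cl, _ = fused_with_centerline
        assert mp.signed_distance(mesh, cl.points).max() <= 0.05

    def test_arc_length_strictly_increasing(self, fused_with_centerline):
        _, cl, _ = fused_with_centerline
        assert np.all(np.diff(cl.arc_length) > 0)
        assert np.all(cl.radii > 0)

    def test_non_tubular_mesh_rejected(self):
        ball = trimesh.creation.icosphere(2, radius=1.0)
        with pytest.raises(mp.CenterlineError):
            mp.fit_centerline(ball)


class TestParentDiameter:
    def test_cylinder_diameter(self, straight_vessel):
        cl = mp.fit_centerline(straight_vessel)
        d = mp.measure_parent_diameter(straight_vessel, cl,
                                       cl.total_length / 2)
        assert d == pytest.approx(3.0, rel=0.02)

    def test_elliptical_tube_equivalent_diameter(self):
        """Closed form: equivalent diameter of an a x b ellipse section."""
        a, b = 2.0, 1.2
        tube = trimesh.creation.cylinder(radius=1.0, height=20.0,
                                         sections=96)
        tube.apply_scale([a, b, 1.0])
        tube.apply_transform(trimesh.transformations.rotation_matrix(
            math.pi / 2, [0, 1, 0]))
        cl = mp.fit_centerline(tube)
        d = mp.measure_parent_diameter(tube, cl, cl.total_length / 2)
        assert d == pytest.approx(2 * math.sqrt(a * b), rel=0.02)

    def test_rotation_invariance(self, straight_vessel):
        R = trimesh.transformations.rotation_matrix(1.1, [0.3, 1.0, 0.2])
        rot = straight_vessel.copy()
        rot.apply_transform(R)
        cl0 = mp.fit_centerline(straight_vessel)
        cl1 = mp.fit_centerline(rot)
        d0 = mp.measure_parent_diameter(straight_vessel, cl0,
                                        cl0.total_length / 2)
        d1 = mp.measure_parent_diameter(rot, cl1, cl1.total_length / 2)
        assert d0 == pytest.approx(d1, rel=1e-3)

    def test_dome_station_warns_and_measures_clean(self,
                                                   fused_with_centerline):
        mesh, cl, neck = fused_with_centerline
        s_mid = 0.5 * (neck.s_lo + neck.s_hi)
        with pytest.warns(UserWarning, match="dome"):
            d = mp.measure_parent_diameter(mesh, cl, s_mid)
        assert d == pytest.approx(3.0, rel=0.05)


class TestCut1:
    def test_watertight_when_capped(self, cut1_result):
        cropped, _ = cut1_result
        assert cropped.is_watertight

    def test_sleeve_arc_length_equals_diameter(self, fused_with_centerline,
                                               cut1_result):
        mesh, cl, neck = fused_with_centerline
        cropped, d = cut1_result
        dense = mp._resample_polyline(cl.points, 0.1)
        sd = np.concatenate(
            [[0], np.cumsum(np.linalg.norm(np.diff(dense, axis=0), axis=1))])
        dist, idx = cKDTree(dense).query(cropped.vertices)
        near = dist < 1.3 * 1.5
        s_min, s_max = sd[idx[near]].min(), sd[idx[near]].max()
        tol = 0.15  # one remesh edge
        assert neck.s_lo - s_min == pytest.approx(d, abs=3 * 0.15)
        assert s_max - neck.s_hi == pytest.approx(d, abs=3 * 0.15)

    def test_volume_nesting(self, fused_with_centerline, cut1_result):
        mesh, cl, neck = fused_with_centerline
        cropped, _ = cut1_result
        dome = mp.dome_crop(mesh, cl, neck=neck)
        assert dome.is_watertight
        assert mesh.volume > cropped.volume > dome.volume > 0

    def test_zero_sleeve_reproduces_dome_configuration(
            self, fused_with_centerline):
        mesh, cl, neck = fused_with_centerline
        zero = mp.cut1_crop(mesh, cl, mp.CutSpec(0, 0.0))
        dome = mp.dome_crop(mesh, cl, neck=neck)
        assert zero.volume == pytest.approx(dome.volume, rel=1e-6)

    def test_excessive_cut_distance_names_side(self, fused_with_centerline):
        mesh, cl, neck = fused_with_centerline
        with pytest.raises(mp.CropError, match="upstream|downstream"):
            mp.cut1_crop(mesh, cl,
                         mp.CutSpec(0, 50.0,
                                    neck_span=(neck.s_lo, neck.s_hi)))


class TestBranchRemoval:
    def test_small_branch_removed_watertight(self, branch_model):
        out = mp.remove_branches_and_fix(branch_model, max_branch_radius=0.5)
        assert out.is_watertight
        # branch tip reached |y| ~ 4; after removal nothing sticks out there
        assert out.vertices[:, 1].max() < 3.0
        assert branch_model.vertices[:, 1].max() > 3.5

    def test_genus_zero_after_removal(self, branch_model):
        out = mp.remove_branches_and_fix(branch_model, max_branch_radius=0.5)
        assert out.euler_number == 2

    def test_no_branch_is_identity(self, fused_model):
        out = mp.remove_branches_and_fix(fused_model, max_branch_radius=0.5)
        assert len(out.faces) == len(fused_model.faces)
        assert out.area == pytest.approx(fused_model.area, rel=1e-9)

    def test_dome_survives_removal(self, branch_model):
        out = mp.remove_branches_and_fix(branch_model, max_branch_radius=0.5)
        # dome apex region still present
        assert out.vertices[:, 2].max() > 5.0


class TestSmooth:
    def test_zero_iterations_identity(self, fused_model):
        out = mp.smooth(fused_model, 0.5, 0)
        assert np.allclose(out.vertices, fused_model.vertices)

    def test_topology_preserved_and_area_shrinks(self, fused_model):
        out = mp.smooth(fused_model, 0.5, 3)
        assert len(out.vertices) == len(fused_model.vertices)
        assert np.array_equal(out.faces, fused_model.faces)
        assert out.area <= fused_model.area

    def test_sphere_radial_change_bounded(self):
        sphere = trimesh.creation.icosphere(4, radius=1.0)
        out = mp.smooth(sphere, 0.5, 3)
        r = np.linalg.norm(out.vertices, axis=1)
        assert np.abs(r - 1.0).max() < 0.05

    def test_curvature_spread_non_increasing_on_noisy_sphere(self):
        """Umbrella-operator curvature proxy: the max-min spread of the
        discrete Laplacian magnitude shrinks under smoothing."""
        rng = np.random.default_rng(0)
        sphere = trimesh.creation.icosphere(3, radius=2.0)
        noisy = sphere.copy()
        noisy.vertices = noisy.vertices + rng.normal(
            scale=0.02, size=(len(noisy.vertices), 3))

        def spread(m):
            from scipy.sparse import coo_matrix

            e = m.edges_unique
            n = len(m.vertices)
            adj = coo_matrix((np.ones(2 * len(e)),
                              (np.r_[e[:, 0], e[:, 1]],
                               np.r_[e[:, 1], e[:, 0]])),
                             shape=(n, n)).tocsr()
            deg = np.asarray(adj.sum(axis=1)).ravel()
            k = np.linalg.norm(adj @ m.vertices / deg[:, None] - m.vertices,
                               axis=1)
            return k.max() - k.min()

        assert spread(mp.smooth(noisy, 0.5, 3)) <= spread(noisy)


class TestRemesh:
    @pytest.fixture(scope="class")
    def remeshed_sphere(self):
        sphere = trimesh.creation.icosphere(3, radius=2.0)
        return sphere, mp.uniform_remesh(sphere, target_edge=0.15)

    def test_median_edge_in_band(self, remeshed_sphere):
        _, rm = remeshed_sphere
        med = np.median(rm.edges_unique_length)
        assert 0.11 <= med <= 0.19

    def test_watertight_and_area_conserved(self, remeshed_sphere):
        sphere, rm = remeshed_sphere
        assert rm.is_watertight
        assert rm.area == pytest.approx(sphere.area, rel=0.02)

    def test_hausdorff_below_target(self, remeshed_sphere):
        _, rm = remeshed_sphere
        r = np.linalg.norm(rm.vertices, axis=1)
        assert np.abs(r - 2.0).max() < 0.15

    def test_idempotent_within_tolerance(self, remeshed_sphere):
        _, rm = remeshed_sphere
        rm2 = mp.uniform_remesh(rm, target_edge=0.15, iterations=2)
        m1 = np.median(rm.edges_unique_length)
        m2 = np.median(rm2.edges_unique_length)
        assert abs(m2 - m1) / m1 < 0.05

    def test_oversized_target_rejected(self, fused_model):
        with pytest.raises(ValueError):
            mp.uniform_remesh(fused_model, target_edge=5.0)


class TestSTLIO:
    def test_round_trip_preserves_faces(self, fused_model, tmp_path):
        path = tmp_path / "m.stl"
        mp.write_stl(fused_model, path)
        back = mp.read_stl(path)
        assert len(back.faces) == len(fused_model.faces)

    def test_ascii_binary_agree(self, straight_vessel, tmp_path):
        pa, pb = tmp_path / "a.stl", tmp_path / "b.stl"
        mp.write_stl(straight_vessel, pa, ascii_dialect=True)
        mp.write_stl(straight_vessel, pb, ascii_dialect=False)
        ma, mb = mp.read_stl(pa), mp.read_stl(pb)
        assert len(ma.faces) == len(mb.faces)
        assert ma.area == pytest.approx(mb.area, rel=1e-6)

    def test_unit_cube_area(self, tmp_path):
        cube = trimesh.creation.box(extents=[1.0, 1.0, 1.0])
        path = tmp_path / "cube.stl"
        mp.write_stl(cube, path)
        back = mp.read_stl(path)
        assert len(back.faces) == 12
        assert back.area == pytest.approx(6.0, abs=1e-6)

    def test_truncated_binary_reports_offset(self, fused_model, tmp_path):
        path = tmp_path / "trunc.stl"
        mp.write_stl(fused_model, path)
        data = path.read_bytes()
        (tmp_path / "bad.stl").write_bytes(data[:len(data) // 2])
        with pytest.raises(ValueError, match="byte"):
            mp.read_stl(tmp_path / "bad.stl")


class TestPipeline:
    def test_full_preprocess_deterministic_and_watertight(self, fused_model):
        a = mp.preprocess(fused_model, mode="cut1", target_edge=0.3,
                          remesh=True)
        b = mp.preprocess(fused_model, mode="cut1", target_edge=0.3,
                          remesh=True)
        assert a.is_watertight
        assert np.array_equal(a.vertices, b.vertices)

    def test_dome_mode_smaller_than_cut1(self, fused_model):
        dome = mp.preprocess(fused_model, mode="dome", remesh=False)
        cut1 = mp.preprocess(fused_model, mode="cut1", remesh=False)
        assert dome.volume < cut1.volume
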