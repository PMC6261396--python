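"""Silhouettes, overhangs, support volume, cut-plane optimization, pins, shells."""

import numpy as np
import pytest
import shapely
import trimesh
from shapely.geometry import Polygon as ShapelyPolygon
from skimage.draw import polygon as draw_polygon

from tubeprint.buildplan import (
    PinSpec,
    add_pins,
    measure_wall_thickness,
    optimize_cut_plane,
    overhang_faces,
    projected_area,
    support_volume,
    thin_wall_offset,
)
from tubeprint.geometry import GeometryError, Plane, plane_cut, rotation_aligning
from tubeprint.synthetic import ColonSpec, make_colon_mesh


def voxel_support_oracle(mesh, res=0.1, critical_angle=45.0):
    """Dense brute-force support volume: per-cell occupancy columns from
    slice-parity rasterization, gaps below flagged overhang surfaces."""
    lo, hi = mesh.bounds
    xs = np.arange(lo[0] + res / 2, hi[0], res)
    ys = np.arange(lo[1] + res / 2, hi[1], res)
    zs = np.arange(res / 2, hi[2], res)
    X, Y = np.meshgrid(xs, ys, indexing="ij")
    occ = np.zeros((len(xs), len(ys), len(zs)), bool)
    for k, z in enumerate(zs):
        sec = mesh.section(plane_origin=[0, 0, z], plane_normal=[0, 0, 1])
        if sec is None:
            continue
        inside = np.zeros(X.size, bool)
        for ring in sec.discrete:
            if len(ring) < 4:
                continue
            p = ShapelyPolygon(ring[:, :2])
            if not p.is_valid:
                p = p.buffer(0)
            inside ^= shapely.contains_xy(p, X.ravel(), Y.ravel())
        occ[:, :, k] = inside.reshape(X.shape)
    flagged = overhang_faces(mesh, critical_angle=critical_angle)
    tri = mesh.vertices[mesh.faces[flagged]]
    colmap = {}
    for t in tri:
        tx = (t[:, 0] - (lo[0] + res / 2)) / res
        ty = (t[:, 1] - (lo[1] + res / 2)) / res
        rr, cc = draw_polygon(tx, ty, shape=(len(xs), len(ys)))
        n = np.cross(t[1] - t[0], t[2] - t[0])
        if abs(n[2]) < 1e-12:
            continue
        for r, c in zip(rr, cc):
            z = t[0, 2] - ((xs[r] - t[0, 0]) * n[0] + (ys[c] - t[0, 1]) * n[1]) / n[2]
            key = (r, c)
            colmap.setdefault(key, []).append(z)
    total = 0.0
    for (r, c), ztops in colmap.items():
        col = occ[r, c]
        for ztop in ztops:
            kz = int(ztop / res)
            below = np.flatnonzero(col[:kz])
            zb = (below.max() + 1) * res if len(below) else 0.0
            total += max(ztop - zb, 0.0) * res * res
    return total


class TestProjectedArea:
    def test_unit_cube_face_projection(self, unit_cube):
        assert projected_area(unit_cube, Plane([0, 0, 0], [0, 0, 1]),
                              resolution=0.01) == pytest.approx(1.0, rel=0.01)

    def test_elliptic_cylinder_major_axis_silhouette(self, elliptic_tube):
        # plane contains the tube axis (z) and the major axis (x): 2 a L
        area = projected_area(elliptic_tube, Plane([0, 0, 0], [0, 1, 0]),
                              resolution=0.1)
        assert area == pytest.approx(2 * 10 * 50, rel=0.01)

    def test_random_blob_matches_fine_rasterization(self, rng):
        hull = trimesh.convex.convex_hull(rng.normal(scale=8.0, size=(60, 3)))
        plane = Plane([0, 0, 0], rng.normal(size=3))
        coarse = projected_area(hull, plane, resolution=0.25)
        fine = projected_area(hull, plane, resolution=0.1)
        assert coarse == pytest.approx(fine, rel=0.01)


class TestOverhangs:
    def test_cube_on_plate_has_none(self):
        cube = trimesh.creation.box(extents=[10, 10, 10])
        cube.apply_translation([0, 0, 5])
        assert len(overhang_faces(cube)) == 0

    def test_elevated_slab_lower_face_flagged(self):
        slab = trimesh.creation.box(extents=[20, 20, 2])
        slab.apply_translation([0, 0, 11])
        idx = overhang_faces(slab)
        normals = slab.face_normals[idx]
        assert len(idx) == 2
        assert np.allclose(normals[:, 2], -1.0)

    def test_sphere_zone_area_matches_analytic(self, sphere10):
        s = sphere10.copy()
        s.apply_translation([0, 0, 10])
        idx = overhang_faces(s, critical_angle=45.0)
        flagged_area = s.area_faces[idx].sum()
        h = 10 * (1 - np.cos(np.deg2rad(45)))
        assert flagged_area == pytest.approx(2 * np.pi * 10 * h, rel=0.02)


class TestSupportVolume:
    def test_cube_needs_no_support(self):
        cube = trimesh.creation.box(extents=[10, 10, 10])
        cube.apply_translation([0, 0, 5])
        assert support_volume(cube, resolution=0.5).total_volume == 0.0

    def test_slab_on_post_column_geometry(self):
        slab = trimesh.creation.box(extents=[20, 20, 2])
        slab.apply_translation([0, 0, 11])
        post = trimesh.creation.box(extents=[2, 2, 10])
        post.apply_translation([0, 0, 5])
        model = support_volume(trimesh.util.concatenate([slab, post]), resolution=0.25)
        assert model.total_volume == pytest.approx((400 - 4) * 10, rel=0.03)

    def test_dome_down_matches_voxel_oracle(self, sphere10):
        _, bot = plane_cut(sphere10, Plane([0, 0, 0], [0, 0, 1]))
        bot.apply_translation([0, 0, 10])
        model = support_volume(bot, resolution=0.25)
        oracle = voxel_support_oracle(bot, res=0.1)
        assert model.total_volume == pytest.approx(oracle, rel=0.05)

    def test_invariance_under_z_rotation_and_translation(self):
        slab = trimesh.creation.box(extents=[20, 20, 2])
        slab.apply_translation([0, 0, 11])
        post = trimesh.creation.box(extents=[2, 2, 10])
        post.apply_translation([0, 0, 5])
        model = trimesh.util.concatenate([slab, post])
        base = support_volume(model, resolution=0.25).total_volume
        rot = model.copy()
        rot.apply_transform(trimesh.transformations.rotation_matrix(
            np.deg2rad(30), [0, 0, 1]))
        shifted = model.copy()
        shifted.apply_translation([7.3, -4.1, 0])
        assert support_volume(rot, resolution=0.25).total_volume == pytest.approx(base, rel=0.05)
        assert support_volume(shifted, resolution=0.25).total_volume == pytest.approx(base, rel=0.05)

    def test_bad_resolution_rejected(self, unit_cube):
        with pytest.raises(ValueError):
            support_volume(unit_cube, resolution=0.0)


class TestOptimizeCutPlane:
    def test_elliptic_tube_finds_major_axis_plane(self, elliptic_tube):
        axis = np.array([[0, 0, -25.0], [0, 0, 25.0]])
        plan = optimize_cut_plane(elliptic_tube, axis, angle_step=2.0,
                                  support_resolution=0.5)
        # the optimal plane contains the major (x) axis: normal ~ +-y
        assert abs(plan.cut_plane.normal @ [1, 0, 0]) <= np.sin(np.deg2rad(2.0))
        assert plan.build_dir @ plan.cut_plane.normal == pytest.approx(1.0)

    def test_circular_tube_ties_resolve_to_zero_angle(self):
        tube = trimesh.creation.cylinder(radius=10.0, height=50.0, sections=96)
        axis = np.array([[0, 0, -25.0], [0, 0, 25.0]])
        plan = optimize_cut_plane(tube, axis, angle_step=10.0, support_resolution=1.0)
        assert plan.phi_deg == 0.0
        assert plan.total_support_volume == 0.0

    def test_halves_conserve_volume_and_are_watertight(self, elliptic_tube):
        axis = np.array([[0, 0, -25.0], [0, 0, 25.0]])
        plan = optimize_cut_plane(elliptic_tube, axis, angle_step=30.0,
                                  support_resolution=1.0)
        va, vb = (h.volume for h in plan.halves)
        assert va + vb == pytest.approx(elliptic_tube.volume, rel=1e-3)
        assert all(h.is_watertight for h in plan.halves)
        assert all(h.vertices[:, 2].min() == pytest.approx(0.0, abs=1e-9)
                   for h in plan.halves)

    def test_winner_not_beaten_on_own_sweep(self, elliptic_tube):
        axis = np.array([[0, 0, -25.0], [0, 0, 25.0]])
        plan = optimize_cut_plane(elliptic_tube, axis, angle_step=15.0,
                                  support_resolution=1.0, refine=False)
        sweep_supports = [row[1] for row in plan.sweep_table]
        assert plan.total_support_volume <= min(sweep_supports) + 1e-9

    def test_convex_halves_are_self_supporting(self, sphere10):
        # a sphere cut through the centroid and placed cut-face-down has no
        # face steeper than the 45 degree cone: zero support
        axis = np.array([[-10.0, 0, 0], [10.0, 0, 0]])
        plan = optimize_cut_plane(sphere10, axis, angle_step=45.0,
                                  support_resolution=0.5)
        assert plan.total_support_volume == 0.0


@pytest.fixture(scope="module")
def pinned_halves():
    tube = trimesh.creation.cylinder(radius=10.0, height=50.0, sections=64)
    plane = Plane([0, 0, 0], [0, 1, 0])
    pos, neg = plane_cut(tube, plane)
    a, b = add_pins(pos, neg, PinSpec(), plane=plane)
    return pos, neg, a, b, plane


class TestPins:
    def test_outputs_watertight(self, pinned_halves):
        _, _, a, b, _ = pinned_halves
        assert a.is_watertight and b.is_watertight

    def test_boss_volume_delta(self, pinned_halves):
        pos, _, a, _, _ = pinned_halves
        expected = 2 * np.pi * 2.0 ** 2 * 4.0
        assert a.volume - pos.volume == pytest.approx(expected, rel=0.05)

    def test_hole_volume_delta(self, pinned_halves):
        _, neg, _, b, _ = pinned_halves
        expected = -2 * np.pi * 2.1 ** 2 * 4.1
        assert b.volume - neg.volume == pytest.approx(expected, rel=0.05)

    def test_hole_radius_echoes_clearance(self, pinned_halves):
        _, neg, _, b, plane = pinned_halves
        # ring vertices added on the cap plane around each hole center
        new_pts = b.vertices[len(neg.vertices):]
        on_plane = new_pts[np.abs(plane.signed_distance(new_pts)) < 1e-6]
        assert len(on_plane) > 0
        # recover the two hole centers by clustering the new cap vertices
        from scipy.cluster.vq import kmeans2
        cents, labels = kmeans2(on_plane[:, [0, 2]], 2, seed=1)
        radii = [np.linalg.norm(on_plane[labels == k][:, [0, 2]] - cents[k], axis=1).mean()
                 for k in (0, 1)]
        assert np.allclose(radii, 2.1, atol=0.05)

    def test_bosses_at_quarter_fractions(self, pinned_halves):
        pos, _, a, _, plane = pinned_halves
        new_pts = a.vertices[len(pos.vertices):]
        xs = np.sort(np.unique(np.round(new_pts[:, 0], 1)))
        # cut face spans z in [-25, 25] along the tube; principal axis is z
        zc = np.round(new_pts[:, 2], 1)
        lo, hi = -25.0, 25.0
        targets = [lo + 0.25 * (hi - lo), lo + 0.75 * (hi - lo)]
        for t in targets:
            assert np.min(np.abs(zc - t)) <= 2.5

    def test_assembled_pins_clear_the_holes(self, pinned_halves):
        _, _, a, b, _ = pinned_halves
        from tubeprint._proximity import MeshProximity
        boss_pts = a.vertices[a.vertices[:, 1] < -1e-9]  # boss protrudes to -y
        sd, _, _ = MeshProximity(b).signed_distance(boss_pts)
        assert sd.min() >= -1e-9  # nothing penetrates half_b's solid

    def test_margin_violation_rejected(self):
        tube = trimesh.creation.cylinder(radius=4.0, height=30.0, sections=48)
        plane = Plane([0, 0, 0], [0, 1, 0])
        pos, neg = plane_cut(tube, plane)
        with pytest.raises(GeometryError, match="margin"):
            add_pins(pos, neg, PinSpec(radius=2.5), plane=plane)


class TestThinWall:
    def test_sphere_shell_volume(self, sphere10):
        shell = thin_wall_offset(sphere10, 1.0)
        assert shell.is_watertight
        analytic = 4 / 3 * np.pi * (10 ** 3 - 9 ** 3)
        assert shell.volume == pytest.approx(analytic, rel=0.03)

    def test_cylinder_wall_thickness_by_raycast(self):
        spec = ColonSpec(control_points=((0, 0, 0), (50.0, 0, 0)),
                         fold_amplitude=0.0, radius_taper=0.0, base_radius=10.0,
                         n_axial=60, n_theta=64)
        tube, _ = make_colon_mesh(spec)
        shell = thin_wall_offset(tube, 1.0)
        th = measure_wall_thickness(shell, n_samples=500)
        assert np.median(th) == pytest.approx(1.0, abs=0.1)

    def test_zero_thickness_rejected(self, sphere10):
        with pytest.raises(GeometryError):
            thin_wall_offset(sphere10, 0.0)

    def test_overthick_wall_rejected_with_regions(self, sphere10):
        with pytest.raises(GeometryError):
            thin_wall_offset(sphere10, 11.0)
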