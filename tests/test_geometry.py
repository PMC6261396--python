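"""Mesh integrity, healing, measures, plane cuts, and rigid transforms."""

import numpy as np
import pytest
import trimesh

from tubeprint.geometry import (
    GeometryError,
    Plane,
    RigidTransform,
    apply_transform,
    check_integrity,
    count_self_intersections,
    heal,
    mesh_area,
    mesh_volume,
    plane_cut,
)


def brute_force_edge_tally(faces):
    """Independent hash-map tally of boundary / non-manifold edges."""
    counts = {}
    for f in faces:
        for a, b in ((f[0], f[1]), (f[1], f[2]), (f[2], f[0])):
            key = (min(a, b), max(a, b))
            counts[key] = counts.get(key, 0) + 1
    boundary = sum(1 for v in counts.values() if v == 1)
    nonmanifold = sum(1 for v in counts.values() if v > 2)
    return boundary, nonmanifold


class TestCheckIntegrity:
    def test_closed_cube_is_clean(self, unit_cube):
        rep = check_integrity(unit_cube)
        assert rep.watertight
        assert rep.n_boundary_loops == 0
        assert rep.n_nonmanifold_edges == 0
        assert rep.n_degenerate_faces == 0
        assert rep.n_selfintersecting_pairs == 0
        assert rep.winding_consistent

    def test_cube_with_quad_removed_has_one_loop(self, unit_cube):
        m = trimesh.Trimesh(vertices=unit_cube.vertices.copy(),
                            faces=unit_cube.faces[:-2].copy(), process=False)
        rep = check_integrity(m)
        assert not rep.watertight
        assert rep.n_boundary_loops == 1

    @pytest.mark.parametrize("k", [1, 5, 20])
    def test_random_deletions_match_edge_tally(self, sphere10, k, rng):
        keep = np.ones(len(sphere10.faces), dtype=bool)
        keep[rng.choice(len(sphere10.faces), size=k, replace=False)] = False
        m = trimesh.Trimesh(vertices=sphere10.vertices,
                            faces=sphere10.faces[keep], process=False)
        rep = check_integrity(m, check_self_intersections=False)
        boundary_edges, nonmanifold = brute_force_edge_tally(m.faces)
        assert rep.n_nonmanifold_edges == nonmanifold
        # every boundary edge belongs to exactly one loop
        loop_edges = sum(len(loop) for loop in _loops(m))
        assert loop_edges == boundary_edges

    def test_crossing_triangles_detected(self):
        V = np.array([[0, 0, 0], [2, 0, 0], [0, 2, 0],
                      [0.5, 0.5, -1], [0.5, 0.5, 1], [1.5, 1.5, 0.0]])
        m = trimesh.Trimesh(vertices=V, faces=[[0, 1, 2], [3, 4, 5]], process=False)
        assert count_self_intersections(m) == 1

    def test_empty_mesh_rejected(self):
        m = trimesh.Trimesh(vertices=np.zeros((3, 3)),
                            faces=np.zeros((0, 3), dtype=int), process=False)
        with pytest.raises(GeometryError):
            check_integrity(m)


def _loops(m):
    from tubeprint.geometry import boundary_loops
    loops, _ = boundary_loops(m)
    return loops


class TestHeal:
    def test_cube_missing_triangle_restored(self, unit_cube):
        m = trimesh.Trimesh(vertices=unit_cube.vertices.copy(),
                            faces=unit_cube.faces[:-1].copy(), process=False)
        res = heal(m)
        assert res.mesh.is_watertight
        assert res.mesh.volume == pytest.approx(1.0, abs=1e-6)

    def test_zero_area_slivers_removed(self, unit_cube):
        v = unit_cube.vertices.copy()
        f = unit_cube.faces.copy()
        slivers = np.array([[0, 0, 1], [1, 1, 2], [2, 2, 3], [3, 3, 4], [4, 4, 5]])
        m = trimesh.Trimesh(vertices=v, faces=np.vstack([f, slivers]), process=False)
        res = heal(m)
        rep = check_integrity(res.mesh)
        assert rep.n_degenerate_faces == 0
        assert res.n_removed_degenerate == 5

    def test_punched_sphere_volume_recovered(self, sphere10, rng):
        faces = sphere10.faces
        keep = np.ones(len(faces), dtype=bool)
        for seed_face in (10, 600, 1800):
            verts = set(faces[seed_face])
            for j, f in enumerate(faces):
                if verts & set(f):
                    keep[j] = False
        m = trimesh.Trimesh(vertices=sphere10.vertices, faces=faces[keep], process=False)
        holes = len(_loops(m))
        assert holes == 3
        res = heal(m)
        assert res.mesh.is_watertight
        analytic = 4.0 / 3.0 * np.pi * 1000.0
        assert res.mesh.volume == pytest.approx(analytic, rel=0.005)

    def test_heal_is_idempotent_and_never_adds_defects(self, sphere10):
        m = trimesh.Trimesh(vertices=sphere10.vertices,
                            faces=sphere10.faces[:-30], process=False)
        before = check_integrity(m, check_self_intersections=False)
        once = heal(m)
        twice = heal(once.mesh)
        after = check_integrity(once.mesh, check_self_intersections=False)
        assert after.n_boundary_loops <= before.n_boundary_loops
        assert after.defect_count() <= before.defect_count()
        assert np.allclose(np.sort(once.mesh.vertices, axis=0),
                           np.sort(twice.mesh.vertices, axis=0))
        assert len(once.mesh.faces) == len(twice.mesh.faces)

    def test_large_holes_reported_not_patched(self, sphere10):
        m = trimesh.Trimesh(vertices=sphere10.vertices,
                            faces=sphere10.faces[:-60], process=False)
        res = heal(m, max_hole_edges=5)
        assert res.unresolved
        assert not res.mesh.is_watertight


class TestMeasures:
    def test_unit_cube_volume_and_area(self, unit_cube):
        assert mesh_volume(unit_cube) == pytest.approx(1.0, abs=1e-12)
        assert mesh_area(unit_cube) == pytest.approx(6.0, abs=1e-12)

    def test_icosphere_volume_near_analytic(self, sphere10):
        assert mesh_volume(sphere10) == pytest.approx(4188.7902, rel=0.005)

    def test_convex_hull_volume_matches_voxel_oracle(self, rng):
        pts = rng.normal(scale=5.0, size=(50, 3))
        hull = trimesh.convex.convex_hull(pts)
        vol = mesh_volume(hull)
        # voxel-count oracle at 0.2 mm pitch via slice-parity occupancy
        from tubeprint.centerline import _voxelize_interior
        grid, _ = _voxelize_interior(hull, 0.2)
        assert vol == pytest.approx(grid.sum() * 0.2 ** 3, rel=0.02)

    def test_open_mesh_volume_rejected_naming_loops(self, unit_cube):
        m = trimesh.Trimesh(vertices=unit_cube.vertices,
                            faces=unit_cube.faces[:-2], process=False)
        with pytest.raises(GeometryError, match="boundary"):
            mesh_volume(m)


class TestPlaneCut:
    def test_cube_midplane_halves(self, unit_cube):
        pos, neg = plane_cut(unit_cube, Plane([0, 0, 0], [0, 0, 1]))
        assert pos.is_watertight and neg.is_watertight
        assert pos.volume == pytest.approx(0.5, abs=1e-9)
        assert neg.volume == pytest.approx(0.5, abs=1e-9)

    def test_sphere_cap_matches_formula(self, sphere10):
        pos, neg = plane_cut(sphere10, Plane([0, 0, 5.0], [0, 0, 1]))
        h = 5.0
        cap = np.pi * h ** 2 * (3 * 10 - h) / 3.0
        assert pos.volume == pytest.approx(cap, rel=0.01)
        assert pos.volume + neg.volume == pytest.approx(sphere10.volume, rel=1e-3)

    def test_folded_tube_cut_conserves_volume(self, small_colon):
        mesh, _ = small_colon
        c = mesh.vertices.mean(axis=0)
        pos, neg = plane_cut(mesh, Plane(c, [0.3, 0.8, 0.52]))
        assert pos.is_watertight and neg.is_watertight
        assert pos.volume + neg.volume == pytest.approx(mesh.volume, rel=1e-3)

    def test_positive_side_follows_normal(self, unit_cube):
        pos, _ = plane_cut(unit_cube, Plane([0, 0, 0.2], [0, 0, 1]))
        assert pos.vertices[:, 2].min() >= 0.2 - 1e-9

    def test_cut_faces_lie_on_plane(self, sphere10):
        plane = Plane([0, 0, 3.0], [0, 0, 1])
        pos, _ = plane_cut(sphere10, plane)
        near = np.abs(pos.vertices[:, 2] - 3.0) < 0.5
        on = np.abs(pos.vertices[near][:, 2] - 3.0)
        assert (on < 1e-6).any()

    def test_missing_plane_gives_empty_side(self, unit_cube):
        pos, neg = plane_cut(unit_cube, Plane([0, 0, 10.0], [0, 0, 1]))
        assert len(pos.faces) == 0
        assert len(neg.faces) > 0

    def test_flip_normal_swaps_outputs(self, sphere10):
        p = Plane([0, 0, 2.0], [0, 0, 1])
        pos, neg = plane_cut(sphere10, p)
        pos2, neg2 = plane_cut(sphere10, p.flipped())
        assert pos.volume == pytest.approx(neg2.volume, rel=1e-9)
        assert neg.volume == pytest.approx(pos2.volume, rel=1e-9)


class TestRigidTransforms:
    def test_identity_is_bitwise(self, sphere10):
        out = apply_transform(sphere10, RigidTransform.identity())
        assert np.array_equal(out.vertices, sphere10.vertices)

    def test_composition_equals_combined(self, rng):
        t1 = RigidTransform.random(rng)
        t2 = RigidTransform.random(rng)
        pts = rng.normal(size=(50, 3))
        a = t2.apply(t1.apply(pts))
        b = (t2 @ t1).apply(pts)
        assert np.abs(a - b).max() < 1e-12

    def test_random_roundtrip_error_below_1e9(self, rng):
        for _ in range(10):
            t = RigidTransform.random(rng, max_translation=100.0)
            pts = rng.normal(scale=50.0, size=(200, 3))
            back = t.inverse().apply(t.apply(pts))
            assert np.abs(back - pts).max() < 1e-9

    def test_non_orthonormal_rotation_rejected(self):
        with pytest.raises(GeometryError):
            RigidTransform(np.eye(3) * 2.0, np.zeros(3))
        with pytest.raises(GeometryError):
            RigidTransform(np.diag([1.0, 1.0, -1.0]), np.zeros(3))

    def test_volume_and_area_rigid_invariant(self, sphere10, rng):
        t = RigidTransform.random(rng, max_translation=30.0)
        moved = apply_transform(sphere10, t)
        assert mesh_volume(moved) == pytest.approx(mesh_volume(sphere10), rel=1e-9)
        assert mesh_area(moved) == pytest.approx(mesh_area(sphere10), rel=1e-9)
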