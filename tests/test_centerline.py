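"""Medial-axis extraction, span partitioning, and mesh splitting."""

import numpy as np
import pytest

from tubeprint.centerline import (
    Centerline,
    extract_centerline,
    partition_segments,
    split_mesh_by_spans,
)
from tubeprint.geometry import GeometryError, RigidTransform, apply_transform
from tubeprint.synthetic import ColonSpec, make_colon_mesh


@pytest.fixture(scope="module")
def cylinder_centerline(straight_tube):
    mesh, _ = straight_tube
    return mesh, extract_centerline(mesh, voxel_pitch=1.0)


@pytest.fixture(scope="module")
def colon_centerline(small_colon):
    mesh, gt = small_colon
    return mesh, gt, extract_centerline(mesh)


def brute_force_partition(points, max_dev):
    """Independent recursive splitter scanning deviations point by point."""

    def seg_dist(p, a, b):
        ab = b - a
        t = np.clip(np.dot(p - a, ab) / np.dot(ab, ab), 0, 1)
        return np.linalg.norm(p - (a + t * ab))

    breaks = [0, len(points) - 1]

    def rec(i0, i1):
        if i1 - i0 < 2:
            return
        devs = [seg_dist(points[i], points[i0], points[i1]) for i in range(i0 + 1, i1)]
        worst = max(devs)
        if worst <= max_dev:
            return
        split = i0 + 1 + int(np.argmax(devs))
        breaks.append(split)
        rec(i0, split)
        rec(split, i1)

    rec(0, len(points) - 1)
    return sorted(set(breaks))


class TestExtractCenterline:
    def test_cylinder_axis_recovered(self, cylinder_centerline):
        mesh, cl = cylinder_centerline
        off_axis = np.linalg.norm(cl.points[:, 1:], axis=1)
        assert off_axis.max() <= 1.0  # within one voxel of the true axis
        al = cl.arclength
        interior = (al > 10) & (al < al[-1] - 10)
        assert np.all(np.abs(cl.radius[interior] - 10.0) <= 1.0)

    def test_cylinder_endpoints_reach_caps(self, cylinder_centerline):
        mesh, cl = cylinder_centerline
        caps = np.array([[0.0, 0, 0], [100.0, 0, 0]])
        ends = cl.points[[0, -1]]
        d = np.linalg.norm(ends[:, None] - caps[None], axis=2).min(axis=1)
        assert d.max() <= 2.0  # 2 * voxel_pitch

    def test_torus_bend_radius_recovered(self):
        theta = np.linspace(0, np.pi / 2, 8)
        cps = tuple((40 * np.cos(t), 40 * np.sin(t), 0.0) for t in theta)
        spec = ColonSpec(control_points=cps, fold_amplitude=0.0,
                         radius_taper=0.0, base_radius=10.0, n_axial=80, n_theta=48)
        bend, _ = make_colon_mesh(spec)
        cl = extract_centerline(bend, voxel_pitch=1.5)
        P = cl.points[:, :2]
        A = np.column_stack([2 * P, np.ones(len(P))])
        sol, *_ = np.linalg.lstsq(A, (P ** 2).sum(axis=1), rcond=None)
        R = np.sqrt(sol[2] + sol[0] ** 2 + sol[1] ** 2)
        assert R == pytest.approx(40.0, abs=2.0)

    def test_colon_arclength_matches_generator(self, colon_centerline):
        _, gt, cl = colon_centerline
        assert cl.length == pytest.approx(gt.curve_length, rel=0.05)

    def test_non_watertight_rejected(self, sphere10):
        import trimesh
        m = trimesh.Trimesh(vertices=sphere10.vertices,
                            faces=sphere10.faces[:-2], process=False)
        with pytest.raises(GeometryError):
            extract_centerline(m, voxel_pitch=2.0)

    def test_rigid_equivariance(self, straight_tube):
        mesh, _ = straight_tube
        t = RigidTransform.from_axis_angle([0.3, 1.0, 0.2], 35.0, [7.0, -3.0, 11.0])
        moved = apply_transform(mesh, t)
        cl_m = extract_centerline(moved, voxel_pitch=1.5)
        cl = extract_centerline(mesh, voxel_pitch=1.5)
        # compare as point sets against the transformed axis
        ref = t.apply(cl.points)
        d = np.array([np.linalg.norm(ref - p, axis=1).min() for p in cl_m.points])
        assert np.median(d) <= 1.5


class TestPartitionSegments:
    def test_straight_polyline_single_span(self):
        pts = np.column_stack([np.linspace(0, 100, 50), np.zeros(50), np.zeros(50)])
        cl = Centerline(pts, np.full(50, 5.0))
        assert len(partition_segments(cl, 1.0)) == 1

    def test_right_angle_splits_at_corner(self):
        leg1 = np.column_stack([np.linspace(0, 50, 26), np.zeros(26), np.zeros(26)])
        leg2 = np.column_stack([np.full(25, 50.0), np.linspace(2, 50, 25), np.zeros(25)])
        pts = np.vstack([leg1, leg2])
        cl = Centerline(pts, np.full(len(pts), 5.0))
        spans = partition_segments(cl, 5.0)
        assert len(spans) == 2
        corner = spans[0].chord[1]
        assert np.linalg.norm(corner - [50.0, 0.0, 0.0]) <= 3.0

    def test_noisy_helix_matches_bruteforce_oracle(self, rng):
        t = np.linspace(0, 4 * np.pi, 200)
        pts = np.column_stack([30 * np.cos(t), 30 * np.sin(t), 8 * t])
        pts += rng.normal(scale=0.3, size=pts.shape)
        cl = Centerline(pts, np.full(len(pts), 5.0))
        spans = partition_segments(cl, 3.0)
        breaks = [s.index_range[0] for s in spans] + [spans[-1].index_range[1]]
        assert breaks == brute_force_partition(pts, 3.0)

    def test_decreasing_max_dev_never_decreases_spans(self, colon_centerline):
        _, _, cl = colon_centerline
        counts = [len(partition_segments(cl, md)) for md in (20.0, 10.0, 5.0, 2.5, 1.0)]
        assert all(b >= a for a, b in zip(counts, counts[1:]))

    def test_spans_tile_without_gaps(self, colon_centerline):
        _, _, cl = colon_centerline
        spans = partition_segments(cl, 5.0)
        assert spans[0].start_arclength == 0.0
        assert spans[-1].end_arclength == pytest.approx(cl.length)
        for a, b in zip(spans[:-1], spans[1:]):
            assert a.end_arclength == pytest.approx(b.start_arclength)
        for s in spans:
            assert s.max_chord_deviation <= 5.0

    def test_invalid_max_dev_rejected(self, colon_centerline):
        _, _, cl = colon_centerline
        with pytest.raises(ValueError):
            partition_segments(cl, 0.0)


class TestSplitMeshBySpans:
    def test_cylinder_split_in_two_halves(self, cylinder_centerline):
        mesh, cl = cylinder_centerline
        mid = len(cl.points) // 2
        spans = partition_segments(cl, 1000.0)
        # force one interior boundary at the midpoint
        from tubeprint.centerline import SegmentSpan
        al = cl.arclength
        spans = [
            SegmentSpan(0.0, float(al[mid]), np.array([cl.points[0], cl.points[mid]]),
                        0.0, (0, mid)),
            SegmentSpan(float(al[mid]), float(al[-1]),
                        np.array([cl.points[mid], cl.points[-1]]), 0.0,
                        (mid, len(cl.points) - 1)),
        ]
        pieces = split_mesh_by_spans(mesh, cl, spans)
        assert len(pieces) == 2
        for p in pieces:
            assert p.is_watertight
            assert p.volume == pytest.approx(mesh.volume / 2, rel=0.03)
        assert sum(p.volume for p in pieces) == pytest.approx(mesh.volume, rel=5e-3)

    def test_colon_piece_count_and_conservation(self, colon_centerline):
        mesh, _, cl = colon_centerline
        spans = partition_segments(cl, 6.0)
        pieces = split_mesh_by_spans(mesh, cl, spans)
        assert len(pieces) == len(spans)
        for p in pieces:
            assert p.is_watertight
        assert sum(p.volume for p in pieces) == pytest.approx(mesh.volume, rel=5e-3)
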