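"""Foundational mesh geometry: integrity checking, healing, measures, plane cuts.

All coordinates are millimetres in a right-handed frame; after build
orientation the printing plate is the plane z = 0 and the build direction is
+z.  Triangle surfaces are carried by :class:`trimesh.Trimesh` with 0-based
face indices and outward right-hand winding.  STL files carry no units; the
readers in this package assume mm and record that in metadata.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import shapely
import trimesh
from scipy.spatial.transform import Rotation
from shapely.geometry import Polygon


class GeometryError(ValueError):
    """Raised when an operation's geometric preconditions are violated."""


# --------------------------------------------------------------------------
# basic types
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class Plane:
    """An oriented plane given by a point on it and a unit normal."""

    point: np.ndarray
    normal: np.ndarray

    def __post_init__(self):
        p = np.asarray(self.point, dtype=float).reshape(3)
        n = np.asarray(self.normal, dtype=float).reshape(3)
        norm = np.linalg.norm(n)
        if norm < 1e-12:
            raise GeometryError("plane normal has zero length")
        object.__setattr__(self, "point", p)
        object.__setattr__(self, "normal", n / norm)

    def signed_distance(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        return (pts - self.point) @ self.normal

    def basis(self) -> tuple[np.ndarray, np.ndarray]:
        """Orthonormal in-plane axes (u, v) with (u, v, normal) right-handed."""
        n = self.normal
        a = np.zeros(3)
        a[np.argmin(np.abs(n))] = 1.0
        u = np.cross(n, a)
        u /= np.linalg.norm(u)
        v = np.cross(n, u)
        return u, v

    def flipped(self) -> "Plane":
        return Plane(self.point, -self.normal)


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid motion: x -> R x + t with R orthonormal, det R = +1."""

    rotation: np.ndarray
    translation: np.ndarray

    _TOL = 1e-9

    def __post_init__(self):
        R = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        t = np.asarray(self.translation, dtype=float).reshape(3)
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-8):
            raise GeometryError("rotation matrix is not orthonormal")
        if np.linalg.det(R) < 0:
            raise GeometryError("rotation matrix is a reflection (det < 0)")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    @classmethod
    def from_axis_angle(cls, axis, angle_deg: float, translation=(0.0, 0.0, 0.0)) -> "RigidTransform":
        axis = np.asarray(axis, dtype=float)
        axis = axis / np.linalg.norm(axis)
        R = Rotation.from_rotvec(np.deg2rad(angle_deg) * axis).as_matrix()
        return cls(R, np.asarray(translation, dtype=float))

    @classmethod
    def from_matrix(cls, m: np.ndarray) -> "RigidTransform":
        m = np.asarray(m, dtype=float)
        return cls(m[:3, :3], m[:3, 3])

    @classmethod
    def random(cls, rng: np.random.Generator, max_translation: float = 10.0) -> "RigidTransform":
        R = Rotation.random(random_state=rng).as_matrix()
        t = rng.uniform(-max_translation, max_translation, 3)
        return cls(R, t)

    @property
    def matrix(self) -> np.ndarray:
        m = np.eye(4)
        m[:3, :3] = self.rotation
        m[:3, 3] = self.translation
        return m

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, dtype=float)
        return pts @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self after other: (self @ other)(x) = self(other(x))."""
        return RigidTransform(self.rotation @ other.rotation,
                              self.rotation @ other.translation + self.translation)

    def __matmul__(self, other: "RigidTransform") -> "RigidTransform":
        return self.compose(other)

    def inverse(self) -> "RigidTransform":
        Rt = self.rotation.T
        return RigidTransform(Rt, -Rt @ self.translation)

    def rotation_angle_deg(self) -> float:
        """Magnitude of the rotation, in degrees."""
        return float(np.rad2deg(np.linalg.norm(Rotation.from_matrix(self.rotation).as_rotvec())))


@dataclass
class IntegrityReport:
    """Mesh regularity summary: manifoldness, closure, winding, intersections.

    ``watertight`` implies zero boundary loops and zero non-manifold edges.
    """

    watertight: bool
    n_boundary_loops: int
    n_nonmanifold_edges: int
    n_degenerate_faces: int
    n_selfintersecting_pairs: int
    winding_consistent: bool

    @property
    def clean(self) -> bool:
        return (self.watertight and self.winding_consistent
                and self.n_degenerate_faces == 0
                and self.n_selfintersecting_pairs == 0)

    def defect_count(self) -> int:
        return (self.n_boundary_loops + self.n_nonmanifold_edges
                + self.n_degenerate_faces + self.n_selfintersecting_pairs
                + (0 if self.winding_consistent else 1))

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)


@dataclass
class HealResult:
    mesh: trimesh.Trimesh
    unresolved: list = field(default_factory=list)
    n_filled_holes: int = 0
    n_removed_degenerate: int = 0


# --------------------------------------------------------------------------
# edge topology helpers
# --------------------------------------------------------------------------

_DEGENERATE_AREA = 1e-12


def _directed_edges(faces: np.ndarray) -> np.ndarray:
    """All directed half-edges, shape (3F, 2), in face winding order."""
    return np.concatenate([faces[:, [0, 1]], faces[:, [1, 2]], faces[:, [2, 0]]])


def _edge_incidence(faces: np.ndarray):
    """Return (directed_edges, undirected_keys, counts_per_edge_key_index)."""
    de = _directed_edges(faces)
    und = np.sort(de, axis=1)
    keys, inverse, counts = np.unique(und, axis=0, return_inverse=True, return_counts=True)
    return de, keys, inverse, counts


def boundary_loops(mesh: trimesh.Trimesh):
    """Ordered vertex-index loops of the open boundary.

    Returns (loops, unchained) where each loop is a list of vertex indices
    following the face winding direction, and ``unchained`` counts boundary
    edges that could not be chained (non-manifold boundary junctions).
    """
    faces = np.asarray(mesh.faces)
    de, keys, inverse, counts = _edge_incidence(faces)
    boundary_mask = counts[inverse] == 1
    bedges = de[boundary_mask]
    if len(bedges) == 0:
        return [], 0
    nxt: dict[int, list[int]] = {}
    for a, b in bedges:
        nxt.setdefault(int(a), []).append(int(b))
    loops = []
    unchained = 0
    visited = set()
    for a0, b0 in bedges:
        e0 = (int(a0), int(b0))
        if e0 in visited:
            continue
        loop = [int(a0)]
        cur = e0
        ok = False
        for _ in range(len(bedges) + 1):
            visited.add(cur)
            loop.append(cur[1])
            outs = [b for b in nxt.get(cur[1], []) if (cur[1], b) not in visited]
            if not outs:
                # either closed the loop or dead end
                ok = loop[-1] == loop[0]
                break
            cur = (cur[1], outs[0])
        if ok:
            loops.append(loop[:-1])
        else:
            unchained += len(loop) - 1
    return loops, unchained


def _face_areas(mesh: trimesh.Trimesh) -> np.ndarray:
    v = mesh.vertices
    f = mesh.faces
    c = np.cross(v[f[:, 1]] - v[f[:, 0]], v[f[:, 2]] - v[f[:, 0]])
    return 0.5 * np.linalg.norm(c, axis=1)


# --------------------------------------------------------------------------
# self intersections
# --------------------------------------------------------------------------


def _tri_tri_intersects(t1: np.ndarray, t2: np.ndarray, eps: float) -> bool:
    """Möller-style triangle-triangle overlap test (touching within eps ignored)."""
    n2 = np.cross(t2[1] - t2[0], t2[2] - t2[0])
    ln2 = np.linalg.norm(n2)
    if ln2 < _DEGENERATE_AREA:
        return False
    n2 = n2 / ln2
    d1 = (t1 - t2[0]) @ n2
    if np.all(d1 > eps) or np.all(d1 < -eps):
        return False
    n1 = np.cross(t1[1] - t1[0], t1[2] - t1[0])
    ln1 = np.linalg.norm(n1)
    if ln1 < _DEGENERATE_AREA:
        return False
    n1 = n1 / ln1
    d2 = (t2 - t1[0]) @ n1
    if np.all(d2 > eps) or np.all(d2 < -eps):
        return False
    D = np.cross(n1, n2)
    lD = np.linalg.norm(D)
    if lD < 1e-9:
        return _coplanar_tri_overlap(t1, t2, n1, eps)
    D = D / lD

    def interval(t, d):
        p = t @ D
        # snap near-zero distances
        d = np.where(np.abs(d) <= eps, 0.0, d)
        pos = d > 0
        neg = d < 0
        if not pos.any() and not neg.any():
            return None  # fully coplanar within eps
        if not pos.any() or not neg.any():
            # touches the plane only; treat as no crossing interval
            zero = np.flatnonzero(d == 0.0)
            if len(zero) == 0:
                return None
            vals = p[zero]
            return float(vals.min()), float(vals.max())
        ts = []
        for i in range(3):
            for j in range(i + 1, 3):
                if d[i] * d[j] < 0:
                    s = d[i] / (d[i] - d[j])
                    ts.append(p[i] + s * (p[j] - p[i]))
                elif d[i] == 0.0:
                    ts.append(p[i])
                elif d[j] == 0.0:
                    ts.append(p[j])
        if not ts:
            return None
        return float(min(ts)), float(max(ts))

    i1 = interval(t1, d1)
    i2 = interval(t2, d2)
    if i1 is None or i2 is None:
        return _coplanar_tri_overlap(t1, t2, n1, eps)
    lo = max(i1[0], i2[0])
    hi = min(i1[1], i2[1])
    return hi - lo > eps


def _coplanar_tri_overlap(t1, t2, n, eps) -> bool:
    """2D separating-axis test for (near-)coplanar triangles."""
    ax = np.argmax(np.abs(n))
    cols = [i for i in range(3) if i != ax]
    a = t1[:, cols]
    b = t2[:, cols]
    for tri in (a, b):
        for i in range(3):
            edge = tri[(i + 1) % 3] - tri[i]
            axis = np.array([-edge[1], edge[0]])
            la = np.linalg.norm(axis)
            if la < 1e-15:
                continue
            axis = axis / la
            pa = a @ axis
            pb = b @ axis
            if pa.min() >= pb.max() - eps or pb.min() >= pa.max() - eps:
                return False
    return True


def count_self_intersections(mesh: trimesh.Trimesh, eps: float = 1e-9) -> int:
    """Number of intersecting non-adjacent triangle pairs.

    Broad phase: AABB spatial hash; narrow phase: triangle-triangle overlap.
    Pairs sharing a vertex are excluded (fans always touch).
    """
    v = np.asarray(mesh.vertices)
    f = np.asarray(mesh.faces)
    if len(f) < 2:
        return 0
    tris = v[f]
    lo = tris.min(axis=1)
    hi = tris.max(axis=1)
    extents = hi - lo
    cell = max(float(np.median(extents[extents.max(axis=1) > 0].max(axis=1)) if len(extents) else 1.0), 1e-6)
    ilo = np.floor(lo / cell).astype(np.int64)
    ihi = np.floor(hi / cell).astype(np.int64)
    buckets: dict[tuple, list[int]] = {}
    for i in range(len(f)):
        for x in range(ilo[i, 0], ihi[i, 0] + 1):
            for y in range(ilo[i, 1], ihi[i, 1] + 1):
                for z in range(ilo[i, 2], ihi[i, 2] + 1):
                    buckets.setdefault((x, y, z), []).append(i)
    cand = set()
    for members in buckets.values():
        for ii in range(len(members)):
            for jj in range(ii + 1, len(members)):
                cand.add((members[ii], members[jj]))
    count = 0
    fs = [set(face) for face in f]
    for i, j in cand:
        if fs[i] & fs[j]:
            continue
        # AABB reject
        if np.any(lo[i] > hi[j]) or np.any(lo[j] > hi[i]):
            continue
        if _tri_tri_intersects(tris[i], tris[j], eps):
            count += 1
    return count


# --------------------------------------------------------------------------
# integrity & healing
# --------------------------------------------------------------------------


def check_integrity(mesh: trimesh.Trimesh, check_self_intersections: bool = True) -> IntegrityReport:
    """Exact regularity audit of a triangle mesh.

    Counts boundary loops, non-manifold edges (shared by more than two
    faces), degenerate (zero-area) faces and, optionally, intersecting
    triangle pairs; checks winding consistency on interior edges.
    """
    faces = np.asarray(mesh.faces)
    if len(faces) == 0:
        raise GeometryError("mesh has no faces")
    de, keys, inverse, counts = _edge_incidence(faces)
    n_nonmanifold = int(np.sum(counts > 2))
    n_degenerate = int(np.sum(_face_areas(mesh) < _DEGENERATE_AREA))
    loops, unchained = boundary_loops(mesh)
    n_loops = len(loops) + (1 if unchained else 0)
    # winding: each interior edge must appear once per direction
    winding_ok = True
    two = counts == 2
    if two.any():
        # for edges with count 2, check the two directed copies are opposite
        order = np.argsort(inverse, kind="stable")
        sorted_inv = inverse[order]
        sorted_de = de[order]
        starts = np.searchsorted(sorted_inv, np.arange(len(keys)))
        for k in np.flatnonzero(two):
            a = sorted_de[starts[k]]
            b = sorted_de[starts[k] + 1]
            if a[0] == b[0]:
                winding_ok = False
                break
    n_self = count_self_intersections(mesh) if check_self_intersections else 0
    watertight = (n_loops == 0) and (n_nonmanifold == 0) and winding_ok
    return IntegrityReport(
        watertight=bool(watertight),
        n_boundary_loops=n_loops,
        n_nonmanifold_edges=n_nonmanifold,
        n_degenerate_faces=n_degenerate,
        n_selfintersecting_pairs=n_self,
        winding_consistent=bool(winding_ok),
    )


def _best_fit_plane(points: np.ndarray) -> Plane:
    c = points.mean(axis=0)
    _, _, vt = np.linalg.svd(points - c)
    return Plane(c, vt[2])


def triangulate_loop_3d(loop_points: np.ndarray) -> np.ndarray | None:
    """Triangulate a closed 3D loop on its best-fit plane.

    Returns faces as indices into ``loop_points`` (winding follows the loop
    order), or None if the projected loop is not a simple polygon.
    """
    if len(loop_points) < 3:
        return None
    if len(loop_points) == 3:
        return np.array([[0, 1, 2]])
    plane = _best_fit_plane(loop_points)
    u, v = plane.basis()
    pts2 = np.column_stack([(loop_points - plane.point) @ u,
                            (loop_points - plane.point) @ v])
    return _triangulate_region(pts2, [])


def _triangulate_region(outer2d: np.ndarray, holes2d: list) -> np.ndarray | None:
    """Constrained Delaunay triangulation of a polygon with holes.

    Input rings are 2D vertex arrays; output faces index into the
    concatenation [outer2d, *holes2d].  Returns None on invalid polygons.
    """
    try:
        poly = Polygon(outer2d, holes=[np.asarray(h) for h in holes2d])
        if not poly.is_valid or poly.area <= 0:
            return None
        tri = shapely.constrained_delaunay_triangles(poly)
    except Exception:
        return None
    allpts = np.vstack([outer2d] + [np.asarray(h) for h in holes2d]) if holes2d else np.asarray(outer2d)
    index: dict[tuple, int] = {}
    for i, (x, y) in enumerate(allpts):
        index.setdefault((round(float(x), 9), round(float(y), 9)), i)
    # orientation of the outer ring decides the expected triangle winding
    outer_ccw = _ring_signed_area(outer2d) > 0
    faces = []
    for g in tri.geoms:
        coords = list(g.exterior.coords)[:-1]
        if len(coords) != 3:
            return None
        try:
            idx = [index[(round(float(x), 9), round(float(y), 9))] for x, y in coords]
        except KeyError:
            return None
        a, b, c = (allpts[i] for i in idx)
        ccw = (b[0] - a[0]) * (c[1] - a[1]) - (b[1] - a[1]) * (c[0] - a[0]) > 0
        if ccw != outer_ccw:
            idx = [idx[0], idx[2], idx[1]]
        faces.append(idx)
    return np.asarray(faces, dtype=np.int64)


def _ring_signed_area(ring: np.ndarray) -> float:
    x = ring[:, 0]
    y = ring[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def heal(mesh: trimesh.Trimesh, max_hole_edges: int = 100) -> HealResult:
    """Remove degenerate faces, unify winding, and fill small boundary holes.

    Holes with at most ``max_hole_edges`` edges are triangulated closed on
    their best-fit plane; larger holes (which signal a failed segmentation
    rather than a patchable defect) and non-manifold regions are reported in
    ``unresolved``, never silently altered.  Idempotent.
    """
    m = mesh.copy()
    m.merge_vertices()
    areas = _face_areas(m)
    n_deg = int(np.sum(areas < _DEGENERATE_AREA))
    if n_deg:
        m.update_faces(areas >= _DEGENERATE_AREA)
    m.remove_unreferenced_vertices()
    trimesh.repair.fix_normals(m, multibody=True)

    unresolved: list[str] = []
    _, keys, inverse, counts = _edge_incidence(np.asarray(m.faces))
    n_nm = int(np.sum(counts > 2))
    if n_nm:
        unresolved.append(f"{n_nm} non-manifold edges left untouched")

    loops, unchained = boundary_loops(m)
    if unchained:
        unresolved.append(f"{unchained} boundary edges could not be chained into loops")
    n_filled = 0
    new_faces = []
    for loop in loops:
        if len(loop) > max_hole_edges:
            unresolved.append(f"boundary loop with {len(loop)} edges exceeds max_hole_edges={max_hole_edges}")
            continue
        pts = np.asarray(m.vertices[loop])
        tri = triangulate_loop_3d(pts)
        if tri is None:
            unresolved.append(f"boundary loop with {len(loop)} edges could not be triangulated")
            continue
        # cap winding must oppose the directed boundary (the loop follows the
        # existing faces' winding, the patch is on the other side)
        loop_idx = np.asarray(loop)
        patch = loop_idx[tri]
        bset = {(loop[i], loop[(i + 1) % len(loop)]) for i in range(len(loop))}
        flip = any((int(a), int(b)) in bset
                   for a, b, c in patch
                   for a, b in [(a, b), (b, c), (c, a)])
        if flip:
            patch = patch[:, ::-1]
        new_faces.append(patch)
        n_filled += 1
    if new_faces:
        m = trimesh.Trimesh(vertices=m.vertices.copy(),
                            faces=np.vstack([m.faces] + new_faces),
                            process=False)
        m.merge_vertices()
        trimesh.repair.fix_normals(m, multibody=True)
    if m.is_watertight and m.volume < 0:
        m.invert()
    return HealResult(mesh=m, unresolved=unresolved,
                      n_filled_holes=n_filled, n_removed_degenerate=n_deg)


# --------------------------------------------------------------------------
# measures
# --------------------------------------------------------------------------


def _require_watertight(mesh: trimesh.Trimesh, what: str):
    loops, unchained = boundary_loops(mesh)
    if loops or unchained:
        raise GeometryError(
            f"{what} requires a watertight mesh; found {len(loops)} boundary "
            f"loop(s) of sizes {[len(l) for l in loops]} and {unchained} unchained boundary edges")


def mesh_volume(mesh: trimesh.Trimesh) -> float:
    """Enclosed volume in mm^3 by the divergence theorem (positive if outward)."""
    _require_watertight(mesh, "mesh_volume")
    return float(mesh.volume)


def mesh_area(mesh: trimesh.Trimesh) -> float:
    """Total surface area in mm^2."""
    return float(mesh.area)


# --------------------------------------------------------------------------
# plane cut
# --------------------------------------------------------------------------


def _cap_on_plane(mesh: trimesh.Trimesh, plane: Plane, tol: float) -> trimesh.Trimesh:
    """Close all boundary loops lying on ``plane`` with CDT caps.

    Loop nesting (outer contours vs holes, e.g. when cutting a hollow shell)
    is resolved by polygon containment.  Cap vertices are snapped exactly
    onto the plane.
    """
    loops, unchained = boundary_loops(mesh)
    if unchained:
        raise GeometryError("cap failed: non-manifold boundary on the cut")
    v = mesh.vertices.copy()
    onplane = []
    for loop in loops:
        d = plane.signed_distance(v[loop])
        if np.max(np.abs(d)) <= max(tol, 1e-6):
            v[loop] -= np.outer(d, plane.normal)  # snap
            onplane.append(loop)
    if not onplane:
        return mesh
    u, w = plane.basis()
    rings2d = [np.column_stack([(v[l] - plane.point) @ u, (v[l] - plane.point) @ w])
               for l in onplane]
    polys = []
    for r in rings2d:
        try:
            p = Polygon(r)
            if not p.is_valid:
                p = p.buffer(0)
            polys.append(p)
        except Exception:
            raise GeometryError(f"cap failed: cut section loop is not a polygon:\n{r!r}")
    depth = np.zeros(len(polys), dtype=int)
    for i, pi in enumerate(polys):
        for j, pj in enumerate(polys):
            if i != j and pj.contains(pi.representative_point()) and pj.area > pi.area:
                depth[i] += 1
    new_faces = []
    for i in np.flatnonzero(depth % 2 == 0):
        hole_ids = [j for j in range(len(polys))
                    if depth[j] == depth[i] + 1 and polys[i].contains(polys[j].representative_point())]
        ring_ids = [i] + hole_ids
        tri = _triangulate_region(rings2d[i], [rings2d[j] for j in hole_ids])
        if tri is None:
            raise GeometryError(
                "cap triangulation failed; section polygon:\n"
                + "\n".join(repr(rings2d[j]) for j in ring_ids))
        vert_ids = np.concatenate([np.asarray(onplane[j]) for j in ring_ids])
        patch = vert_ids[tri]
        # orient cap outward: the boundary edges in the patch must oppose the
        # directed mesh boundary
        bset = {(a, b) for l in (onplane[j] for j in ring_ids)
                for a, b in zip(l, l[1:] + l[:1])}
        flip = any((int(a), int(b)) in bset
                   for f in patch for a, b in ((f[0], f[1]), (f[1], f[2]), (f[2], f[0])))
        if flip:
            patch = patch[:, ::-1]
        new_faces.append(patch)
    out = trimesh.Trimesh(vertices=v, faces=np.vstack([mesh.faces] + new_faces),
                          process=False)
    out.merge_vertices()
    return out


def plane_cut(mesh: trimesh.Trimesh, plane: Plane, cap: bool = True,
              tol: float = 1e-6) -> tuple[trimesh.Trimesh, trimesh.Trimesh]:
    """Split a watertight mesh by a plane into (positive-side, negative-side).

    The positive-side mesh is the one the plane normal points into.  With
    ``cap=True`` both halves are closed watertight with planar caps; their
    volumes sum to the input volume.  A plane missing the mesh yields one
    empty mesh (zero faces).
    """
    _require_watertight(mesh, "plane_cut")
    halves = []
    for sign in (1.0, -1.0):
        piece = trimesh.intersections.slice_mesh_plane(
            mesh, plane_normal=sign * plane.normal, plane_origin=plane.point, cap=False)
        if piece is None or len(piece.faces) == 0:
            halves.append(trimesh.Trimesh(vertices=np.zeros((0, 3)),
                                          faces=np.zeros((0, 3), dtype=int), process=False))
            continue
        piece = trimesh.Trimesh(vertices=piece.vertices, faces=piece.faces, process=False)
        piece.merge_vertices()
        if cap:
            piece = _cap_on_plane(piece, plane, tol)
        halves.append(piece)
    return halves[0], halves[1]


# --------------------------------------------------------------------------
# transforms
# --------------------------------------------------------------------------


def apply_transform(obj, t: RigidTransform):
    """Apply a rigid motion to a mesh or an (n, 3) point array (copy)."""
    if isinstance(obj, trimesh.Trimesh):
        return trimesh.Trimesh(vertices=t.apply(obj.vertices),
                               faces=obj.faces.copy(), process=False)
    return t.apply(obj)


def rotation_aligning(a: np.ndarray, b: np.ndarray) -> RigidTransform:
    """Rigid rotation mapping direction a onto direction b (about their common normal)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    a = a / np.linalg.norm(a)
    b = b / np.linalg.norm(b)
    vv = np.cross(a, b)
    c = float(np.dot(a, b))
    if np.linalg.norm(vv) < 1e-12:
        if c > 0:
            return RigidTransform.identity()
        # opposite: rotate 180 deg about any perpendicular axis
        p = Plane(np.zeros(3), a)
        u, _ = p.basis()
        return RigidTransform.from_axis_angle(u, 180.0)
    axis = vv / np.linalg.norm(vv)
    angle = np.rad2deg(np.arctan2(np.linalg.norm(vv), c))
    return RigidTransform.from_axis_angle(axis, angle)
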