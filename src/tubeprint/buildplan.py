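"""Per-segment build planning: self-supporting cut planes, supports, pins.

The governing manufacturing criterion for free-form tubular replicas on a
single-nozzle FFF machine: split each near-linear segment by a plane through
its axis chosen so that both halves print cut-face-down with minimal (ideally
zero) support material.  The plane is scanned over its angle about the axis;
candidates are ranked lexicographically by (1) total support volume of both
placed halves, (2) projected envelope area on the plane (maximized — the
"maximum in-plane surface" criterion), (3) maximum build height (minimized).
The slicing direction is orthogonal to the cut plane, so ``build_dir`` is the
plane normal.

Supports are modelled as vertical columns under overhang faces down to the
plate or the first surface below, quantified on an xy grid — the same
"iteratively check the added support volume" acceptance loop used when such
parts are planned manually.  The critical overhang angle defaults to 45
degrees, the de-facto FFF rule.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import trimesh
from shapely.geometry import LineString, Point, Polygon
from skimage.draw import polygon as _draw_polygon

from tubeprint._proximity import MeshProximity
from tubeprint.geometry import (
    GeometryError,
    Plane,
    RigidTransform,
    _triangulate_region,
    boundary_loops,
    plane_cut,
    rotation_aligning,
)


# --------------------------------------------------------------------------
# silhouette / projected area
# --------------------------------------------------------------------------


def projected_area(mesh: trimesh.Trimesh, plane: Plane, resolution: float = 0.25) -> float:
    """Silhouette area of the mesh projected along the plane normal (mm^2).

    The union of the projected faces is rasterized at ``resolution`` mm
    pixels; exact polygon unions are fragile on dirty organic meshes, and
    the rasterization error is oracle-tested to stay below 1 %.
    """
    u, v = plane.basis()
    V = np.asarray(mesh.vertices) - plane.point
    pts2 = np.column_stack([V @ u, V @ v])
    lo = pts2.min(axis=0) - resolution
    hi = pts2.max(axis=0) + resolution
    shape = (int(np.ceil((hi[0] - lo[0]) / resolution)) + 1,
             int(np.ceil((hi[1] - lo[1]) / resolution)) + 1)
    grid = np.zeros(shape, dtype=bool)
    # pixel i covers centre lo + (i + 0.5) * resolution: centre sampling
    # avoids the half-pixel inflation of boundary-aligned shapes
    tri2 = (pts2[mesh.faces] - lo) / resolution - 0.5
    for t in tri2:
        rr, cc = _draw_polygon(t[:, 0], t[:, 1], shape=shape)
        grid[rr, cc] = True
    return float(grid.sum()) * resolution ** 2


# --------------------------------------------------------------------------
# overhangs & supports
# --------------------------------------------------------------------------


@dataclass
class SupportModel:
    """Support columns under overhang faces, on an xy grid."""

    critical_angle: float
    overhang_faces: np.ndarray
    columns: dict                  # (ix, iy) -> list of (z_bottom, z_top)
    total_volume: float
    resolution: float

    def columns_csv(self, path):
        rows = ["ix,iy,z_bottom,z_top"]
        for (ix, iy), gaps in sorted(self.columns.items()):
            for zb, zt in gaps:
                rows.append(f"{ix},{iy},{zb:.6f},{zt:.6f}")
        with open(path, "w") as fh:
            fh.write("\n".join(rows) + "\n")


def overhang_faces(mesh: trimesh.Trimesh, build_dir=(0, 0, 1.0),
                   critical_angle: float = 45.0, plate_tol: float = 1e-6) -> np.ndarray:
    """Indices of faces that need support when printing along ``build_dir``.

    A face is an overhang iff its outward normal points downward and the
    angle between the normal and the straight-down direction is smaller than
    (90 deg - critical_angle): at the 45 deg default, anything steeper than a
    45 deg wall prints unsupported.  Faces resting on the plate (within
    ``plate_tol`` of the lowest point) are excluded.
    """
    b = np.asarray(build_dir, dtype=float)
    b = b / np.linalg.norm(b)
    n = np.asarray(mesh.face_normals)
    down = n @ b
    cos_thresh = np.cos(np.deg2rad(90.0 - critical_angle))
    flagged = (down < 0) & (-down > cos_thresh)
    # the plate is the height-0 plane along build_dir (parts are plate-placed)
    heights = np.asarray(mesh.vertices) @ b
    face_top = heights[mesh.faces].max(axis=1)
    flagged &= face_top > plate_tol
    return np.flatnonzero(flagged)


def support_volume(mesh: trimesh.Trimesh, build_dir=(0, 0, 1.0),
                   resolution: float = 0.5, critical_angle: float = 45.0) -> SupportModel:
    """Support material volume for a part resting on the plate (z = 0).

    For every xy grid cell under a flagged overhang face, the gap from the
    overhang surface down to the plate or to the first mesh surface below is
    a support column; the total is the sum of cell_area x gap heights.
    """
    if resolution <= 0:
        raise ValueError("resolution must be positive")
    b = np.asarray(build_dir, dtype=float)
    b = b / np.linalg.norm(b)
    if not np.allclose(b, [0, 0, 1]):
        # rotate into plate coordinates
        rot = rotation_aligning(b, [0, 0, 1.0])
        mesh = trimesh.Trimesh(vertices=rot.apply(mesh.vertices), faces=mesh.faces,
                               process=False)
    V = np.asarray(mesh.vertices, dtype=float)
    if V[:, 2].min() < -1e-6:
        raise GeometryError("support_volume expects the part above the plate (min z >= 0)")
    F = np.asarray(mesh.faces)
    normals = np.asarray(
        trimesh.Trimesh(vertices=V, faces=F, process=False).face_normals)
    over = set(overhang_faces(trimesh.Trimesh(vertices=V, faces=F, process=False),
                              (0, 0, 1.0), critical_angle).tolist())

    lo = V[:, :2].min(axis=0) - resolution
    hi = V[:, :2].max(axis=0) + resolution
    shape = (int(np.ceil((hi[0] - lo[0]) / resolution)) + 1,
             int(np.ceil((hi[1] - lo[1]) / resolution)) + 1)
    # crossings per cell: (cell_flat_index, z, is_overhang, is_down)
    cells = []
    zs = []
    overs = []
    downs = []
    tri = V[F]
    for fi in range(len(F)):
        nz = normals[fi, 2]
        if abs(nz) < 1e-9:
            continue  # vertical face: no vertical crossing area
        t2 = (tri[fi][:, :2] - lo) / resolution - 0.5
        rr, cc = _draw_polygon(t2[:, 0], t2[:, 1], shape=shape)
        if len(rr) == 0:
            continue
        # z of the face plane at each cell center
        p0 = tri[fi][0]
        n = normals[fi]
        x = lo[0] + (rr + 0.5) * resolution
        y = lo[1] + (cc + 0.5) * resolution
        z = p0[2] - ((x - p0[0]) * n[0] + (y - p0[1]) * n[1]) / n[2]
        cells.append(rr.astype(np.int64) * shape[1] + cc.astype(np.int64))
        zs.append(z)
        overs.append(np.full(len(rr), fi in over))
        downs.append(np.full(len(rr), nz < 0))
    model = SupportModel(critical_angle=critical_angle,
                         overhang_faces=np.asarray(sorted(over), dtype=np.int64),
                         columns={}, total_volume=0.0, resolution=resolution)
    if not cells:
        return model
    cells = np.concatenate(cells)
    zs = np.concatenate(zs)
    overs = np.concatenate(overs)
    downs = np.concatenate(downs)
    order = np.lexsort((zs, cells))
    cells, zs, overs, downs = cells[order], zs[order], overs[order], downs[order]
    total = 0.0
    columns: dict = {}
    starts = np.concatenate([[0], np.flatnonzero(np.diff(cells)) + 1, [len(cells)]])
    dedup_tol = 1e-9
    for s0, s1 in zip(starts[:-1], starts[1:]):
        z = zs[s0:s1]
        ov = overs[s0:s1]
        dn = downs[s0:s1]
        cell = cells[s0]
        gaps = []
        for i in range(len(z)):
            if not (ov[i] and dn[i]):
                continue
            below = z[:i][z[:i] < z[i] - dedup_tol]
            zb = float(below.max()) if len(below) else 0.0
            gap = float(z[i]) - zb
            if gap > dedup_tol:
                gaps.append((zb, float(z[i])))
        if gaps:
            key = (int(cell // shape[1]), int(cell % shape[1]))
            columns[key] = gaps
            total += sum(zt - zb for zb, zt in gaps)
    model.columns = columns
    model.total_volume = float(total * resolution ** 2)
    return model


# --------------------------------------------------------------------------
# cut-plane optimization
# --------------------------------------------------------------------------


@dataclass
class SegmentPlan:
    """The chosen build plan for one printable segment."""

    segment_mesh: trimesh.Trimesh
    axis: np.ndarray                    # (2, 3) chord endpoints
    phi_deg: float                      # plane angle about the axis
    cut_plane: Plane                    # in segment coordinates
    build_dir: np.ndarray               # = cut_plane.normal (slicing orthogonal to the cut)
    halves: tuple                       # two meshes placed cut-face-down on z = 0
    placement_transforms: tuple         # RigidTransforms that placed them
    halves_cut_pose: tuple              # the same halves in the original (assembled) pose
    projected_area: float
    support_volumes: tuple              # per half, mm^3
    max_heights: tuple                  # per half, mm
    sweep_table: list                   # [(phi, total_support, projected_area, max_height)]

    @property
    def total_support_volume(self) -> float:
        return float(sum(self.support_volumes))

    def to_json(self) -> str:
        return json.dumps({
            "phi_deg": self.phi_deg,
            "cut_plane": {"point": self.cut_plane.point.tolist(),
                          "normal": self.cut_plane.normal.tolist()},
            "build_dir": self.build_dir.tolist(),
            "projected_area_mm2": self.projected_area,
            "support_volume_mm3": list(self.support_volumes),
            "max_height_mm": list(self.max_heights),
            "sweep_table": [[round(x, 6) for x in row] for row in self.sweep_table],
        }, indent=2, sort_keys=True)


def _axis_frame(axis: np.ndarray):
    a0, a1 = np.asarray(axis, dtype=float)
    d = a1 - a0
    d = d / np.linalg.norm(d)
    helper = Plane(a0, d)
    e1, e2 = helper.basis()
    return a0, d, e1, e2


def _place_cut_face_down(half: trimesh.Trimesh, plane_normal: np.ndarray,
                         cap_outward_sign: float) -> tuple[trimesh.Trimesh, RigidTransform]:
    """Rotate so the cap's outward direction becomes -z, then drop onto z=0."""
    rot = rotation_aligning(cap_outward_sign * plane_normal, [0, 0, -1.0])
    v = rot.apply(half.vertices)
    shift = np.array([0.0, 0.0, -v[:, 2].min()])
    placed = trimesh.Trimesh(vertices=v + shift, faces=half.faces.copy(), process=False)
    return placed, RigidTransform(rot.rotation, rot.translation + shift)


def evaluate_cut_plane(mesh: trimesh.Trimesh, plane: Plane,
                       critical_angle: float = 45.0,
                       support_resolution: float = 1.0):
    """Cut, place both halves cut-face-down, and measure the objective.

    Returns (total_support, placed_halves, cut_halves, transforms, heights)
    or None when the plane produces no valid two-sided cut.
    """
    try:
        pos, neg = plane_cut(mesh, plane, cap=True)
    except GeometryError:
        return None
    if len(pos.faces) == 0 or len(neg.faces) == 0:
        return None
    placed = []
    transforms = []
    supports = []
    heights = []
    for half, sign in ((pos, -1.0), (neg, +1.0)):
        p, t = _place_cut_face_down(half, plane.normal, sign)
        sm = support_volume(p, (0, 0, 1.0), resolution=support_resolution,
                            critical_angle=critical_angle)
        placed.append(p)
        transforms.append(t)
        supports.append(sm.total_volume)
        heights.append(float(p.vertices[:, 2].max()))
    return (float(sum(supports)), tuple(supports), tuple(placed), (pos, neg),
            tuple(transforms), tuple(heights))


def optimize_cut_plane(mesh: trimesh.Trimesh, axis: np.ndarray,
                       angle_step: float = 2.0,
                       critical_angle: float = 45.0,
                       support_resolution: float = 1.0,
                       area_resolution: float = 0.25,
                       refine: bool = True) -> SegmentPlan:
    """Scan planes containing the segment axis for the self-supporting cut.

    Planes at angles phi in [0, 180) about the axis are ranked
    lexicographically: minimal total support volume of both cut-face-down
    halves, then maximal projected envelope area, then minimal build height.
    Ties keep the lowest angle.  A golden-section refinement around the best
    grid angle polishes the support objective when it is not already zero.
    """
    a0, d, e1, e2 = _axis_frame(axis)
    mid = 0.5 * (np.asarray(axis[0], dtype=float) + np.asarray(axis[1], dtype=float))

    def plane_at(phi_deg):
        phi = np.deg2rad(phi_deg)
        return Plane(mid, np.cos(phi) * e1 + np.sin(phi) * e2)

    sweep = []
    best = None
    # tie tolerances absorb mesh-faceting and rasterization noise so that a
    # rotationally symmetric segment ties at every angle (lowest phi wins)
    tol_s = max(support_resolution ** 2 * 1e-3, 1e-9)
    rel_a = 2e-3
    rel_h = 1e-3
    phis = np.arange(0.0, 180.0, angle_step)
    for phi in phis:
        plane = plane_at(phi)
        res = evaluate_cut_plane(mesh, plane, critical_angle, support_resolution)
        if res is None:
            continue
        total_s, supports, placed, cut_halves, transforms, heights = res
        area = projected_area(mesh, plane, area_resolution)
        hmax = max(heights)
        sweep.append((float(phi), total_s, area, hmax))
        cand = (phi, total_s, supports, area, hmax, placed, cut_halves, transforms, plane)
        if best is None:
            best = cand
            continue
        _, bs, _, ba, bh, *_ = best
        tol_a = rel_a * max(area, ba)
        tol_h = max(rel_h * max(hmax, bh), 1e-6)
        if total_s < bs - tol_s:
            best = cand
        elif abs(total_s - bs) <= tol_s:
            if area > ba + tol_a:
                best = cand
            elif abs(area - ba) <= tol_a and hmax < bh - tol_h:
                best = cand
    if best is None:
        raise GeometryError("no angle produced a valid two-sided cut of the segment")

    if refine and best[1] > tol_s:
        lo_phi = best[0] - angle_step
        hi_phi = best[0] + angle_step
        invphi = (np.sqrt(5) - 1) / 2
        cache = {}

        def f(phi):
            phi = float(np.mod(phi, 180.0))
            if phi not in cache:
                res = evaluate_cut_plane(mesh, plane_at(phi), critical_angle,
                                         support_resolution)
                cache[phi] = (np.inf,) if res is None else res
            return cache[phi][0]

        a, b = lo_phi, hi_phi
        c = b - invphi * (b - a)
        dd = a + invphi * (b - a)
        for _ in range(12):
            if f(c) < f(dd):
                b = dd
            else:
                a = c
            c = b - invphi * (b - a)
            dd = a + invphi * (b - a)
        phi_ref = float(np.mod(0.5 * (a + b), 180.0))
        res = evaluate_cut_plane(mesh, plane_at(phi_ref), critical_angle,
                                 support_resolution)
        if res is not None and res[0] < best[1]:
            total_s, supports, placed, cut_halves, transforms, heights = res
            plane = plane_at(phi_ref)
            area = projected_area(mesh, plane, area_resolution)
            sweep.append((phi_ref, total_s, area, max(heights)))
            best = (phi_ref, total_s, supports, area, max(heights), placed,
                    cut_halves, transforms, plane)

    phi, total_s, supports, area, hmax, placed, cut_halves, transforms, plane = best
    heights = tuple(float(p.vertices[:, 2].max()) for p in placed)
    return SegmentPlan(
        segment_mesh=mesh, axis=np.asarray(axis, dtype=float),
        phi_deg=float(phi), cut_plane=plane, build_dir=plane.normal.copy(),
        halves=placed, placement_transforms=transforms,
        halves_cut_pose=cut_halves,
        projected_area=float(area),
        support_volumes=tuple(float(s) for s in supports),
        max_heights=heights, sweep_table=sweep)


# --------------------------------------------------------------------------
# closing pins
# --------------------------------------------------------------------------


@dataclass
class PinSpec:
    """Cylindrical alignment pins across the cut face."""

    radius: float = 2.0
    height: float = 4.0
    clearance: float = 0.1
    count: int = 2
    placement_fractions: tuple = (0.25, 0.75)
    n_sides: int = 32

    def __post_init__(self):
        if self.clearance < 0:
            raise ValueError("clearance must be non-negative")
        if len(self.placement_fractions) != self.count:
            self.placement_fractions = tuple(
                (i + 1) / (self.count + 1) for i in range(self.count))


def _cap_region(mesh: trimesh.Trimesh, plane: Plane, tol: float = 1e-6):
    """Remove the planar cap faces; return (open mesh faces mask, cap loops 2D)."""
    V = np.asarray(mesh.vertices)
    d = plane.signed_distance(V)
    onplane_v = np.abs(d) <= tol
    F = np.asarray(mesh.faces)
    cap_faces = onplane_v[F].all(axis=1)
    if not cap_faces.any():
        raise GeometryError("no planar cap faces found on the given plane")
    return cap_faces


def _pin_centers(outer2d: np.ndarray, spec: PinSpec, needed_margin: float):
    """Pin centers along the cap's principal axis, nudged inside the polygon."""
    poly = Polygon(outer2d)
    if not poly.is_valid:
        poly = poly.buffer(0)
    pts = outer2d - outer2d.mean(axis=0)
    _, _, vt = np.linalg.svd(pts, full_matrices=False)
    pa = vt[0]
    proj = pts @ pa
    t0, t1 = proj.min(), proj.max()
    centers = []
    for frac in spec.placement_fractions:
        t = t0 + frac * (t1 - t0)
        base = outer2d.mean(axis=0) + t * pa
        # chord of the polygon at this station, perpendicular to the axis
        perp = np.array([-pa[1], pa[0]])
        span = np.linalg.norm(outer2d.max(axis=0) - outer2d.min(axis=0)) * 2
        line = LineString([base - span * perp, base + span * perp])
        inter = line.intersection(poly)
        segs = getattr(inter, "geoms", [inter])
        best_mid, best_len = None, -1.0
        for seg in segs:
            if seg.length > best_len:
                best_len = seg.length
                best_mid = np.asarray(seg.interpolate(0.5, normalized=True).coords[0])
        if best_mid is None:
            raise GeometryError("cut face too small for pin placement")
        margin = poly.boundary.distance(Point(best_mid))
        if margin < needed_margin:
            raise GeometryError(
                f"pin at fraction {frac} has margin {margin:.2f} mm < required "
                f"{needed_margin:.2f} mm; reduce pin radius or count")
        centers.append(best_mid)
    return centers


def _rebuild_with_circles(mesh, plane, circle_centers, radius, depth,
                          outward_sign, spec_sides, tol=1e-6):
    """Retriangulate the planar cap with circular openings plus barrel walls.

    ``depth`` > 0 adds a protruding boss (cylinder capped at -depth along the
    cap outward direction is a hole; positive bosses use outward direction).
    ``outward_sign`` is +1 when the cap's outward normal equals plane.normal.
    """
    V = np.asarray(mesh.vertices).copy()
    F = np.asarray(mesh.faces)
    cap_faces = _cap_region(mesh, plane, tol)
    open_mesh = trimesh.Trimesh(vertices=V, faces=F[~cap_faces], process=False)
    loops, unchained = boundary_loops(open_mesh)
    if unchained:
        raise GeometryError("cap boundary is non-manifold")
    u, w = plane.basis()
    # classify loops on the plane
    rings = []
    ring_vids = []
    for loop in loops:
        d = plane.signed_distance(V[loop])
        if np.max(np.abs(d)) > max(tol, 1e-6):
            continue
        rings.append(np.column_stack([(V[loop] - plane.point) @ u,
                                      (V[loop] - plane.point) @ w]))
        ring_vids.append(np.asarray(loop))
    if not rings:
        raise GeometryError("no cap boundary loops on the plane")
    areas = [abs(_signed_area(r)) for r in rings]
    outer_i = int(np.argmax(areas))
    hole_is = [i for i in range(len(rings)) if i != outer_i]

    theta = np.linspace(0, 2 * np.pi, spec_sides, endpoint=False)
    circ2d = [c + radius * np.column_stack([np.cos(theta), np.sin(theta)])
              for c in circle_centers]
    new_vid_start = len(V)
    circ_vids = []
    newV = [V]
    for c2 in circ2d:
        pts3 = plane.point + np.outer(c2[:, 0], u) + np.outer(c2[:, 1], w)
        circ_vids.append(np.arange(new_vid_start, new_vid_start + spec_sides))
        new_vid_start += spec_sides
        newV.append(pts3)
    tri = _triangulate_region(rings[outer_i],
                              [rings[i] for i in hole_is] + circ2d)
    if tri is None:
        raise GeometryError("cap retriangulation with pin circles failed")
    all_vids = np.concatenate([ring_vids[outer_i]]
                              + [ring_vids[i] for i in hole_is] + circ_vids)
    cap_tris = all_vids[tri]
    # orient the cap outward
    normal_dir = outward_sign * plane.normal
    Vall = np.vstack(newV)
    a, b, c = (Vall[cap_tris[:, k]] for k in range(3))
    nn = np.cross(b - a, c - a).sum(axis=0)
    if nn @ normal_dir < 0:
        cap_tris = cap_tris[:, ::-1]

    # barrel + far disk for each circle; axial direction: bosses protrude
    # along the cap outward direction, holes burrow opposite to it
    axial = normal_dir * depth
    far_center_ids = []
    barrel_faces = []
    for ci, vids in enumerate(circ_vids):
        far_ids = np.arange(new_vid_start, new_vid_start + spec_sides)
        new_vid_start += spec_sides
        newV.append(Vall[vids] + axial)
        center_id = new_vid_start
        new_vid_start += 1
        c3 = plane.point + np.outer([circle_centers[ci][0]], u)[0] \
            + np.outer([circle_centers[ci][1]], w)[0] + axial
        newV.append(c3[None, :])
        far_center_ids.append(center_id)
        for j in range(spec_sides):
            j2 = (j + 1) % spec_sides
            barrel_faces.append([vids[j], vids[j2], far_ids[j2]])
            barrel_faces.append([vids[j], far_ids[j2], far_ids[j]])
            barrel_faces.append([center_id, far_ids[j2], far_ids[j]])
    Vall = np.vstack(newV)
    faces = np.vstack([F[~cap_faces], cap_tris, np.asarray(barrel_faces)])
    out = trimesh.Trimesh(vertices=Vall, faces=faces, process=False)
    out.merge_vertices()
    trimesh.repair.fix_normals(out)
    if out.is_watertight and out.volume < 0:
        out.invert()
    return out


def _signed_area(ring):
    x, y = ring[:, 0], ring[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def add_pins(half_a: trimesh.Trimesh, half_b: trimesh.Trimesh,
             spec: PinSpec | None = None,
             plane: Plane | None = None) -> tuple[trimesh.Trimesh, trimesh.Trimesh]:
    """Add cylindrical closing pins across the congruent planar cut face.

    Bosses of the pin radius/height are unioned onto half_a's cut face;
    matching holes (radius + clearance, depth + clearance) are sunk into
    half_b at the same in-plane positions, so the reassembled replica
    self-aligns.  Both halves must share the cut plane (the pose produced by
    :func:`tubeprint.geometry.plane_cut`); pass ``plane`` explicitly if the
    halves were moved.  The CSG is exact: the planar cap is retriangulated
    with circular openings and cylindrical walls are appended.
    """
    spec = spec or PinSpec()
    if plane is None:
        plane = _detect_shared_plane(half_a, half_b)
    # half_a is on the positive side (cap outward = -normal)
    u, w = plane.basis()
    cap_faces_a = _cap_region(half_a, plane)
    Fa = np.asarray(half_a.faces)[cap_faces_a]
    ring = np.asarray(half_a.vertices)[np.unique(Fa)]
    outer2d = np.column_stack([(ring - plane.point) @ u, (ring - plane.point) @ w])
    hull_margin = spec.radius + spec.clearance + spec.radius  # one pin-radius margin
    # placement uses the hull of the cap points; exactness comes from the
    # margin check against the true cap polygon inside _pin_centers
    cap_loop = _cap_outline(half_a, plane)
    centers = _pin_centers(cap_loop, spec, hull_margin)

    sign_a = float(np.sign(np.asarray(half_a.face_normals)[cap_faces_a.argmax()] @ plane.normal))
    a_out = _rebuild_with_circles(half_a, plane, centers, spec.radius,
                                  spec.height, sign_a, spec.n_sides)
    b_out = _rebuild_with_circles(half_b, plane, centers,
                                  spec.radius + spec.clearance,
                                  -(spec.height + spec.clearance), -sign_a,
                                  spec.n_sides)
    return a_out, b_out


def _cap_outline(mesh, plane, tol=1e-6):
    cap_faces = _cap_region(mesh, plane, tol)
    open_mesh = trimesh.Trimesh(vertices=mesh.vertices,
                                faces=np.asarray(mesh.faces)[~cap_faces], process=False)
    loops, _ = boundary_loops(open_mesh)
    u, w = plane.basis()
    best, area = None, -1.0
    V = np.asarray(mesh.vertices)
    for loop in loops:
        d = plane.signed_distance(V[loop])
        if np.max(np.abs(d)) > max(tol, 1e-6):
            continue
        r2 = np.column_stack([(V[loop] - plane.point) @ u, (V[loop] - plane.point) @ w])
        a = abs(_signed_area(r2))
        if a > area:
            area, best = a, r2
    if best is None:
        raise GeometryError("no planar cap outline found")
    return best


def _detect_shared_plane(half_a, half_b) -> Plane:
    """Find the congruent planar cut face shared by the two halves."""
    for mesh in (half_a,):
        fn = np.asarray(mesh.face_normals)
        V = np.asarray(mesh.vertices)
        F = np.asarray(mesh.faces)
        areas = trimesh.Trimesh(vertices=V, faces=F, process=False).area_faces
        # cluster by quantized normal + offset
        keys = {}
        for fi in range(len(F)):
            n = fn[fi]
            off = float(n @ V[F[fi, 0]])
            key = (tuple(np.round(n, 4)), round(off, 3))
            keys.setdefault(key, 0.0)
            keys[key] += areas[fi]
        (nk, off), _ = max(keys.items(), key=lambda kv: kv[1])
        n = np.asarray(nk, dtype=float)
        n /= np.linalg.norm(n)
        point = n * off
        # orient so half_a is on the positive side (cap outward = -n)
        centroid = V.mean(axis=0)
        if (centroid - point) @ n < 0:
            n = -n
        return Plane(point, n)
    raise GeometryError("could not detect a shared cut plane")


# --------------------------------------------------------------------------
# thin-wall shell
# --------------------------------------------------------------------------


def _angle_weighted_vertex_normals(mesh: trimesh.Trimesh) -> np.ndarray:
    V = np.asarray(mesh.vertices)
    F = np.asarray(mesh.faces)
    fn = np.asarray(mesh.face_normals)
    out = np.zeros_like(V)
    for k in range(3):
        i0 = F[:, k]
        e1 = V[F[:, (k + 1) % 3]] - V[i0]
        e2 = V[F[:, (k + 2) % 3]] - V[i0]
        cosang = np.einsum("ij,ij->i", e1, e2) / np.maximum(
            np.linalg.norm(e1, axis=1) * np.linalg.norm(e2, axis=1), 1e-30)
        ang = np.arccos(np.clip(cosang, -1, 1))
        np.add.at(out, i0, fn * ang[:, None])
    return out / np.maximum(np.linalg.norm(out, axis=1, keepdims=True), 1e-30)


def thin_wall_offset(mesh: trimesh.Trimesh, thickness: float) -> trimesh.Trimesh:
    """Hollow a watertight solid into a shell of the given wall thickness.

    The inner surface is the outer one offset inward along angle-weighted
    vertex normals; the shell is the outer surface plus the inverted inner
    surface (two closed components, jointly watertight).  Offsets that would
    self-intersect at high-curvature folds are rejected with the offending
    regions listed.
    """
    if thickness <= 0:
        raise GeometryError("wall thickness must be positive (t=0 would be the identity)")
    if not mesh.is_watertight:
        raise GeometryError("thin_wall_offset requires a watertight mesh")
    vn = _angle_weighted_vertex_normals(mesh)
    inner_v = np.asarray(mesh.vertices) - thickness * vn
    inner = trimesh.Trimesh(vertices=inner_v, faces=np.asarray(mesh.faces).copy(),
                            process=False)
    # detect collapsed/flipped faces from over-tight curvature
    fn_out = np.asarray(mesh.face_normals)
    fn_in = np.asarray(inner.face_normals)
    flipped = np.einsum("ij,ij->i", fn_out, fn_in) <= 0
    if flipped.any():
        spots = inner.triangles[flipped].mean(axis=1)
        raise GeometryError(
            f"inward offset self-intersects at {int(flipped.sum())} face(s), e.g. near\n"
            f"{np.round(spots[:5], 2)}; wall too thick for the local curvature")
    if inner.volume <= 0:
        raise GeometryError("inward offset collapsed the cavity; wall too thick")
    inner_inverted = inner.copy()
    inner_inverted.invert()
    shell = trimesh.util.concatenate([mesh.copy(), inner_inverted])
    return trimesh.Trimesh(vertices=shell.vertices, faces=shell.faces, process=False)


def measure_wall_thickness(shell: trimesh.Trimesh, n_samples: int = 500,
                           seed: int = 0) -> np.ndarray:
    """Ray-cast style thickness sampling of a two-surface shell.

    Samples the outer surface and measures the distance to the inner
    surface; returns the per-sample thicknesses.
    """
    comps = shell.split(only_watertight=False)
    if len(comps) < 2:
        raise GeometryError("shell does not have separate outer and inner surfaces")
    comps = sorted(comps, key=lambda c: abs(c.volume), reverse=True)
    outer, inner = comps[0], comps[1]
    from tubeprint.synthetic import sample_surface  # local import: avoid cycle
    rng = np.random.default_rng(seed)
    pts, _ = sample_surface(outer, n_samples, rng)
    d, _, _, _ = MeshProximity(inner).closest(pts)
    return d
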