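"""Deterministic synthetic fixtures: folded tubes, volumes, simulated scans.

Real inputs to this pipeline are patient image stacks and structured-light
scans, which cannot ship with a code repository.  These generators emulate
their geometric character: a colon-like tube swept along a curvilinear axis
with haustral folds so that no two transversal sections are equal, its
rasterization into an anisotropic slice volume, and surface scans with a
known rigid offset, noise, and optional systematic offset field.  Every
generator is seeded and bit-reproducible, and stores its ground truth so
recovery tests can close the loop.

Haustral folds are modelled as r(s, theta) = r0(s) * (1 + a sin(k_s s) *
(1 + b cos(3 theta))): three angular lobes approximate the taeniae-bounded
haustra.  The parameters describe the fixture, not anatomy.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import shapely
import trimesh
from scipy.interpolate import CubicSpline
from shapely.geometry import Polygon as _Poly

from tubeprint.deviation import PointCloud
from tubeprint.geometry import GeometryError, RigidTransform
from tubeprint.reconstruction import ImageVolume

# a gently folded, sigmoid-like default axis roughly 300 mm long, sized like
# the printed parts (tube radius ~15-25 mm)
_DEFAULT_CONTROL_POINTS = (
    (0.0, 0.0, 0.0),
    (60.0, 25.0, 10.0),
    (120.0, -10.0, 30.0),
    (180.0, 30.0, 45.0),
    (240.0, 0.0, 70.0),
    (290.0, -25.0, 80.0),
)


@dataclass
class ColonSpec:
    """Parameters of the synthetic folded-tube fixture."""

    seed: int = 42
    control_points: tuple = _DEFAULT_CONTROL_POINTS
    base_radius: float = 16.0
    radius_taper: float = 0.15          # relative linear change of r0 along s
    fold_amplitude: float = 0.12        # a: relative longitudinal modulation
    fold_cycles: float = 9.0            # k_s: sin cycles along the full length
    angular_amplitude: float = 0.35     # b: strength of the 3-lobe modulation
    wall_thickness: float = 1.0         # hollow variant (mm)
    n_axial: int = 220
    n_theta: int = 48

    def r0(self, s_norm: np.ndarray) -> np.ndarray:
        return self.base_radius * (1.0 + self.radius_taper * (s_norm - 0.5))

    def radius(self, s_norm: np.ndarray, theta: np.ndarray) -> np.ndarray:
        a, b = self.fold_amplitude, self.angular_amplitude
        mod = 1.0 + a * np.sin(2 * np.pi * self.fold_cycles * s_norm) * (1.0 + b * np.cos(3 * theta))
        return self.r0(s_norm) * mod


@dataclass
class ColonGroundTruth:
    curve: np.ndarray              # densely sampled axis points (mm)
    curve_length: float            # arclength (mm)
    spec: ColonSpec
    section_area: np.ndarray       # per-axial-sample cross-section area (mm^2)

    @property
    def quadrature_volume(self) -> float:
        """Tube volume by quadrature of cross-section areas along the axis."""
        seg = np.linalg.norm(np.diff(self.curve, axis=0), axis=1)
        mid = 0.5 * (self.section_area[1:] + self.section_area[:-1])
        return float(np.sum(mid * seg))


def _parallel_transport_frames(points: np.ndarray):
    """Minimal-twist orthonormal frames (t, u, v) along a polyline."""
    tangents = np.gradient(points, axis=0)
    tangents /= np.linalg.norm(tangents, axis=1, keepdims=True)
    t0 = tangents[0]
    a = np.zeros(3)
    a[np.argmin(np.abs(t0))] = 1.0
    u = np.cross(t0, a)
    u /= np.linalg.norm(u)
    us = [u]
    for i in range(1, len(points)):
        t_prev, t_cur = tangents[i - 1], tangents[i]
        c = np.cross(t_prev, t_cur)
        nc = np.linalg.norm(c)
        if nc < 1e-12:
            us.append(us[-1])
            continue
        axis = c / nc
        ang = np.arctan2(nc, float(t_prev @ t_cur))
        K = np.array([[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]])
        R = np.eye(3) + np.sin(ang) * K + (1 - np.cos(ang)) * (K @ K)
        un = R @ us[-1]
        un = un - (un @ t_cur) * t_cur
        us.append(un / np.linalg.norm(un))
    us = np.asarray(us)
    vs = np.cross(tangents, us)
    return tangents, us, vs


def make_colon_mesh(spec: ColonSpec | None = None) -> tuple[trimesh.Trimesh, ColonGroundTruth]:
    """Watertight genus-0 folded tube, plus its analytic ground truth.

    The surface is a sweep of modulated cross-sections along a cubic-spline
    axis through the control points, closed by end-cap fans.  A spec whose
    bends are tighter than the local tube radius would self-intersect and is
    rejected with the violating arclength.
    """
    spec = spec or ColonSpec()
    cps = np.asarray(spec.control_points, dtype=float)
    chord = np.concatenate([[0.0], np.cumsum(np.linalg.norm(np.diff(cps, axis=0), axis=1))])
    spl = CubicSpline(chord / chord[-1], cps, axis=0)
    # densify then re-parameterize ~uniformly by arclength
    tt = np.linspace(0, 1, 4 * spec.n_axial)
    dense = spl(tt)
    seg = np.linalg.norm(np.diff(dense, axis=0), axis=1)
    al = np.concatenate([[0.0], np.cumsum(seg)])
    s_targets = np.linspace(0, al[-1], spec.n_axial)
    curve = np.column_stack([np.interp(s_targets, al, dense[:, d]) for d in range(3)])
    length = float(al[-1])
    s_norm = s_targets / length

    # self-intersection guard: bend radius must exceed the local max radius
    t_, u_, v_ = _parallel_transport_frames(curve)
    d2 = np.gradient(np.gradient(curve, s_targets, axis=0), s_targets, axis=0)
    curvature = np.linalg.norm(d2, axis=1)
    theta_chk = np.linspace(0, 2 * np.pi, 36, endpoint=False)
    rmax_s = spec.radius(s_norm[:, None], theta_chk[None, :]).max(axis=1)
    bad = curvature * rmax_s > 0.95
    if bad.any():
        s_bad = s_targets[bad]
        raise GeometryError(
            f"tube would self-intersect: bend tighter than the tube radius at "
            f"arclength(s) {np.round(s_bad, 1)} mm")

    theta = np.linspace(0, 2 * np.pi, spec.n_theta, endpoint=False)
    r = spec.radius(s_norm[:, None], theta[None, :])
    ring = (curve[:, None, :]
            + r[:, :, None] * (np.cos(theta)[None, :, None] * u_[:, None, :]
                               + np.sin(theta)[None, :, None] * v_[:, None, :]))
    ns, nt = spec.n_axial, spec.n_theta
    verts = ring.reshape(-1, 3)
    faces = []
    for i in range(ns - 1):
        for j in range(nt):
            a = i * nt + j
            b = i * nt + (j + 1) % nt
            c = (i + 1) * nt + j
            d = (i + 1) * nt + (j + 1) % nt
            faces.append([a, b, d])
            faces.append([a, d, c])
    # end caps: fans to the ring centroids
    c0 = len(verts)
    c1 = len(verts) + 1
    verts = np.vstack([verts, curve[0], curve[-1]])
    for j in range(nt):
        faces.append([c0, (j + 1) % nt, j])
        base = (ns - 1) * nt
        faces.append([c1, base + j, base + (j + 1) % nt])
    mesh = trimesh.Trimesh(vertices=verts, faces=np.asarray(faces), process=False)
    trimesh.repair.fix_normals(mesh)
    if mesh.volume < 0:
        mesh.invert()
    # polygonal cross-section area: 1/2 sum r_j r_{j+1} sin(dtheta)
    dtheta = 2 * np.pi / nt
    area = 0.5 * np.sum(r * np.roll(r, -1, axis=1) * np.sin(dtheta), axis=1)
    gt = ColonGroundTruth(curve=curve, curve_length=length, spec=spec, section_area=area)
    return mesh, gt


def rasterize_to_volume(mesh: trimesh.Trimesh,
                        spacing: tuple[float, float, float] = (0.5, 0.5, 3.0),
                        noise_sd: float = 0.0, contrast: float = 100.0,
                        seed: int = 0, pad: float = 2.0) -> ImageVolume:
    """Binary-contrast rasterization of a solid into an image volume.

    Inside/outside is decided per slice by even-odd parity of the section
    contours (exact for watertight inputs); inside voxels take ``contrast``,
    outside 0, and seeded Gaussian noise of ``noise_sd`` is added on top.
    The slice step (third spacing component) emulates the coarse transversal
    step of clinical stacks (3 mm by default).
    """
    if min(spacing) <= 0:
        raise ValueError("spacing must be positive")
    lo, hi = mesh.bounds
    xs = np.arange(lo[0] - pad, hi[0] + pad, spacing[0])
    ys = np.arange(lo[1] - pad, hi[1] + pad, spacing[1])
    zs = np.arange(lo[2] - pad, hi[2] + pad, spacing[2])
    X, Y = np.meshgrid(xs, ys, indexing="ij")
    vol = np.zeros((len(xs), len(ys), len(zs)), dtype=np.float32)
    for k, z in enumerate(zs):
        sec = mesh.section(plane_origin=[0, 0, z], plane_normal=[0, 0, 1])
        if sec is None:
            continue
        inside = np.zeros(X.size, dtype=bool)
        for ringpts in sec.discrete:
            if len(ringpts) < 4:
                continue
            poly = _Poly(ringpts[:, :2])
            if not poly.is_valid:
                poly = poly.buffer(0)
            inside ^= shapely.contains_xy(poly, X.ravel(), Y.ravel())
        vol[:, :, k] = np.where(inside.reshape(X.shape), contrast, 0.0)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        vol = vol + rng.normal(0.0, noise_sd, vol.shape).astype(np.float32)
    return ImageVolume(vol, spacing, origin=[xs[0], ys[0], zs[0]])


@dataclass
class ScanGroundTruth:
    transform: RigidTransform      # applied to the sampled points
    offsets: np.ndarray            # signed normal displacement per point (mm)
    face_index: np.ndarray


def sample_surface(mesh: trimesh.Trimesh, n_points: int, rng: np.random.Generator):
    """Area-weighted uniform surface samples with their face normals."""
    areas = mesh.area_faces
    probs = areas / areas.sum()
    fi = rng.choice(len(areas), size=n_points, p=probs)
    r1 = np.sqrt(rng.uniform(size=n_points))
    r2 = rng.uniform(size=n_points)
    tri = mesh.vertices[mesh.faces[fi]]
    pts = ((1 - r1)[:, None] * tri[:, 0]
           + (r1 * (1 - r2))[:, None] * tri[:, 1]
           + (r1 * r2)[:, None] * tri[:, 2])
    return pts, fi


def simulate_scan(mesh: trimesh.Trimesh, n_points: int = 50_000,
                  noise_sd: float = 0.04,
                  transform: RigidTransform | None = None,
                  offset_field=None,
                  seed: int = 0) -> tuple[PointCloud, ScanGroundTruth]:
    """Emulated structured-light acquisition of a printed part.

    Surface points are sampled area-uniformly, displaced along the outward
    normal by ``offset_field`` (a constant, an (n,)-array, or a callable of
    the points — emulating print shape error), perturbed with isotropic
    Gaussian noise at the scanner's accuracy (0.04 mm class), and moved by a
    rigid ``transform`` standing in for the unknown scanner pose.
    """
    if n_points < 100:
        raise ValueError("simulate_scan needs at least 100 points")
    rng = np.random.default_rng(seed)
    transform = transform or RigidTransform.identity()
    pts, fi = sample_surface(mesh, n_points, rng)
    normals = np.asarray(mesh.face_normals)[fi]
    if offset_field is None:
        offsets = np.zeros(n_points)
    elif callable(offset_field):
        offsets = np.asarray(offset_field(pts), dtype=float).reshape(-1)
    else:
        offsets = np.broadcast_to(np.asarray(offset_field, dtype=float), (n_points,)).copy()
    pts = pts + offsets[:, None] * normals
    if noise_sd > 0:
        pts = pts + rng.normal(0.0, noise_sd, pts.shape)
    pts = transform.apply(pts)
    cloud = PointCloud(pts, normals @ transform.rotation.T,
                       metadata={"n_points": n_points, "noise_sd": noise_sd, "seed": seed})
    return cloud, ScanGroundTruth(transform=transform, offsets=offsets, face_index=fi)
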