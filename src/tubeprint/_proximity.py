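"""Exact point-to-triangle-mesh proximity queries.

Broad phase: a KD-tree over triangle centroids bounds the search radius;
narrow phase: exact point-triangle distance over the candidate set, so the
result equals the exhaustive all-triangle minimum.  Signs use angle-weighted
pseudo-normals (Baerentzen & Aanaes), which are robust at edges and
vertices where a single face normal can give the wrong side.
"""

from __future__ import annotations

import numpy as np
import trimesh
from scipy.spatial import cKDTree


def closest_point_on_triangles(points: np.ndarray, tri: np.ndarray):
    """Closest point on triangle i to point i, vectorized over pairs.

    points: (n, 3); tri: (n, 3, 3).  Returns (closest (n,3), (s, t) barycentric
    along edges AB, AC).
    """
    A = tri[:, 0]
    E0 = tri[:, 1] - A
    E1 = tri[:, 2] - A
    D = A - points
    a = np.einsum("ij,ij->i", E0, E0)
    b = np.einsum("ij,ij->i", E0, E1)
    c = np.einsum("ij,ij->i", E1, E1)
    d = np.einsum("ij,ij->i", E0, D)
    e = np.einsum("ij,ij->i", E1, D)
    det = np.maximum(a * c - b * b, 1e-30)
    s = b * e - c * d
    t = b * d - a * e

    S = np.empty_like(s)
    T = np.empty_like(t)

    # region classification (Eberly)
    inside = (s + t <= det) & (s >= 0) & (t >= 0)
    S[inside] = s[inside] / det[inside]
    T[inside] = t[inside] / det[inside]

    r = ~inside
    # work elementwise on the remaining entries (vectorized with masks)
    with np.errstate(divide="ignore", invalid="ignore"):
        m1 = r & (s + t <= det) & (s < 0) & (t >= 0)   # region 3 or 2-ish: edge AC
        tt = np.clip(-e / np.maximum(c, 1e-30), 0.0, 1.0)
        S[m1] = 0.0
        T[m1] = tt[m1]

        m2 = r & (s + t <= det) & (t < 0) & (s >= 0)   # edge AB
        ss = np.clip(-d / np.maximum(a, 1e-30), 0.0, 1.0)
        S[m2] = ss[m2]
        T[m2] = 0.0

        m3 = r & (s + t <= det) & (s < 0) & (t < 0)    # vertex A side
        S[m3] = np.clip((-d / np.maximum(a, 1e-30))[m3], 0.0, 1.0)
        T[m3] = 0.0
        fix = m3 & (d >= 0) & (e < 0)
        T[fix] = np.clip((-e / np.maximum(c, 1e-30))[fix], 0.0, 1.0)
        S[fix] = 0.0

        m4 = r & (s + t > det)
        # region 1/2/6: closest on edge BC or at corners
        numer = (c + e - b - d)
        denom = np.maximum(a - 2 * b + c, 1e-30)
        ss_bc = np.clip(numer / denom, 0.0, 1.0)
        # candidate on BC
        Sbc = ss_bc
        Tbc = 1.0 - ss_bc
        # candidate clamped on AB (t=0) and AC (s=0)
        Sab = np.clip(-d / np.maximum(a, 1e-30), 0.0, 1.0)
        Tac = np.clip(-e / np.maximum(c, 1e-30), 0.0, 1.0)

    if m4.any():
        idx = np.flatnonzero(m4)
        cand_s = np.stack([Sbc[idx], Sab[idx], np.zeros(len(idx))], axis=1)
        cand_t = np.stack([Tbc[idx], np.zeros(len(idx)), Tac[idx]], axis=1)
        P = points[idx]
        best = None
        dists = np.empty((len(idx), 3))
        for k in range(3):
            C = A[idx] + cand_s[:, k, None] * E0[idx] + cand_t[:, k, None] * E1[idx]
            dists[:, k] = np.einsum("ij,ij->i", C - P, C - P)
        kbest = np.argmin(dists, axis=1)
        S[idx] = cand_s[np.arange(len(idx)), kbest]
        T[idx] = cand_t[np.arange(len(idx)), kbest]

    closest = A + S[:, None] * E0 + T[:, None] * E1
    return closest, S, T


class MeshProximity:
    """Reusable exact nearest-surface-point queries against one mesh."""

    def __init__(self, mesh: trimesh.Trimesh):
        self.mesh = mesh
        self.V = np.asarray(mesh.vertices, dtype=float)
        self.F = np.asarray(mesh.faces)
        self.tri = self.V[self.F]
        # broad phase runs on a subdivided copy: a few oversized triangles
        # (e.g. planar caps) would otherwise inflate the search radius for
        # every query.  Subdivision does not change the surface.
        sub_tri, parent = self._subdivide_for_search(self.tri)
        self._sub_tri = sub_tri
        self._parent = parent
        self.centroids = sub_tri.mean(axis=1)
        self.tree = cKDTree(self.centroids)
        self.rmax = float(np.linalg.norm(
            sub_tri - self.centroids[:, None, :], axis=2).max(initial=0.0))
        self._pseudo = None

    @staticmethod
    def _subdivide_for_search(tri: np.ndarray, max_ratio: float = 2.0):
        radii = np.linalg.norm(tri - tri.mean(axis=1, keepdims=True), axis=2).max(axis=1)
        target = max(float(np.median(radii)) * max_ratio, 1e-9)
        tris = list(tri)
        parent = list(range(len(tri)))
        out_t, out_p = [], []
        while tris:
            t = tris.pop()
            p = parent.pop()
            c = t.mean(axis=0)
            if np.linalg.norm(t - c, axis=1).max() <= target or len(out_t) + len(tris) > 40 * len(tri):
                out_t.append(t)
                out_p.append(p)
                continue
            # longest-edge bisection
            e = [np.linalg.norm(t[1] - t[0]), np.linalg.norm(t[2] - t[1]),
                 np.linalg.norm(t[0] - t[2])]
            k = int(np.argmax(e))
            a, b, cthird = t[k], t[(k + 1) % 3], t[(k + 2) % 3]
            m = 0.5 * (a + b)
            tris.append(np.array([a, m, cthird]))
            parent.append(p)
            tris.append(np.array([m, b, cthird]))
            parent.append(p)
        return np.asarray(out_t), np.asarray(out_p, dtype=np.int64)

    # ---- pseudo-normals -------------------------------------------------
    def _build_pseudonormals(self):
        fn = np.asarray(self.mesh.face_normals, dtype=float)
        nv = len(self.V)
        vert_n = np.zeros((nv, 3))
        for k in range(3):
            i0 = self.F[:, k]
            e1 = self.V[self.F[:, (k + 1) % 3]] - self.V[i0]
            e2 = self.V[self.F[:, (k + 2) % 3]] - self.V[i0]
            cosang = np.einsum("ij,ij->i", e1, e2) / np.maximum(
                np.linalg.norm(e1, axis=1) * np.linalg.norm(e2, axis=1), 1e-30)
            ang = np.arccos(np.clip(cosang, -1, 1))
            np.add.at(vert_n, i0, fn * ang[:, None])
        norms = np.linalg.norm(vert_n, axis=1, keepdims=True)
        vert_n = vert_n / np.maximum(norms, 1e-30)
        edge_n: dict[tuple, np.ndarray] = {}
        for fi, f in enumerate(self.F):
            for a, b in ((f[0], f[1]), (f[1], f[2]), (f[2], f[0])):
                key = (min(a, b), max(a, b))
                edge_n[key] = edge_n.get(key, 0.0) + fn[fi]
        for key in edge_n:
            v = edge_n[key]
            edge_n[key] = v / max(np.linalg.norm(v), 1e-30)
        self._pseudo = (fn, vert_n, edge_n)

    # ---- queries --------------------------------------------------------
    def closest(self, points: np.ndarray, k0: int = 8):
        """Exact nearest surface point for each query.

        Returns (distance, closest_point, face_index, (s, t) barycentric).
        """
        P = np.atleast_2d(np.asarray(points, dtype=float))
        n = len(P)
        k0 = min(k0, len(self.centroids))
        _, nearest = self.tree.query(P, k=k0)
        nearest = np.atleast_2d(nearest)
        # upper bound from candidate sub-triangles
        cand = nearest.ravel()
        reps = np.repeat(np.arange(n), nearest.shape[1])
        cp, _, _ = closest_point_on_triangles(P[reps], self._sub_tri[cand])
        d2 = np.einsum("ij,ij->i", cp - P[reps], cp - P[reps]).reshape(n, -1)
        ub = np.sqrt(d2.min(axis=1))
        # gather every sub-triangle whose centroid lies within ub + rmax:
        # the true minimizer must be among them
        best_d = np.full(n, np.inf)
        best_sub = np.zeros(n, dtype=np.int64)
        groups = self.tree.query_ball_point(P, ub + self.rmax + 1e-12)
        flat_f = []
        flat_p = []
        for i, g in enumerate(groups):
            flat_f.extend(g)
            flat_p.extend([i] * len(g))
        flat_f = np.asarray(flat_f, dtype=np.int64)
        flat_p = np.asarray(flat_p, dtype=np.int64)
        cp, _, _ = closest_point_on_triangles(P[flat_p], self._sub_tri[flat_f])
        dd = np.sqrt(np.einsum("ij,ij->i", cp - P[flat_p], cp - P[flat_p]))
        order = np.argsort(dd, kind="stable")
        for o in order[::-1]:
            i = flat_p[o]
            best_d[i] = dd[o]
            best_sub[i] = flat_f[o]
        # re-solve on the parent faces for exact barycentric features
        best_f = self._parent[best_sub]
        best_cp, S, T = closest_point_on_triangles(P, self.tri[best_f])
        best_d = np.sqrt(np.einsum("ij,ij->i", best_cp - P, best_cp - P))
        return best_d, best_cp, best_f, (S, T)

    def signed_distance(self, points: np.ndarray):
        """Signed distance, positive outside the surface.

        The sign comes from the pseudo-normal of the nearest feature (face,
        edge or vertex).  Returns (signed_distance, closest_point, face_index).
        """
        if self._pseudo is None:
            self._build_pseudonormals()
        fn, vert_n, edge_n = self._pseudo
        P = np.atleast_2d(np.asarray(points, dtype=float))
        d, cp, fi, (s, t) = self.closest(P)
        normals = np.empty((len(P), 3))
        tol = 1e-9
        for i in range(len(P)):
            f = self.F[fi[i]]
            si, ti = s[i], t[i]
            ui = 1.0 - si - ti
            onA = si < tol and ti < tol
            onB = ui < tol and ti < tol
            onC = ui < tol and si < tol
            if onA or onB or onC:
                v = f[0] if onA else (f[1] if onB else f[2])
                normals[i] = vert_n[v]
            elif ti < tol:      # edge AB
                normals[i] = edge_n[(min(f[0], f[1]), max(f[0], f[1]))]
            elif si < tol:      # edge AC
                normals[i] = edge_n[(min(f[0], f[2]), max(f[0], f[2]))]
            elif ui < tol:      # edge BC
                normals[i] = edge_n[(min(f[1], f[2]), max(f[1], f[2]))]
            else:
                normals[i] = fn[fi[i]]
        signs = np.where(np.einsum("ij,ij->i", P - cp, normals) >= 0, 1.0, -1.0)
        return signs * d, cp, fi

    def contains(self, points: np.ndarray) -> np.ndarray:
        sd, _, _ = self.signed_distance(points)
        return sd < 0
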