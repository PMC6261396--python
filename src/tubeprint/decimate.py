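"""Quadric-error-metric edge-collapse decimation.

A compact implementation of Garland–Heckbert simplification used by
:func:`tubeprint.reconstruction.smooth_and_decimate`.  Collapses are ranked
by quadric error with optimal vertex placement; a collapse is rejected if it
would break the manifold link condition or flip a face normal, so
watertightness of closed inputs is preserved.
"""

from __future__ import annotations

import heapq

import numpy as np
import trimesh


def _face_quadric(v0, v1, v2):
    n = np.cross(v1 - v0, v2 - v0)
    area = 0.5 * np.linalg.norm(n)
    if area < 1e-14:
        return np.zeros((4, 4))
    n = n / (2.0 * area)
    d = -np.dot(n, v0)
    p = np.append(n, d)
    return area * np.outer(p, p)


def _optimal_point(Q, va, vb):
    A = Q[:3, :3]
    b = -Q[:3, 3]
    try:
        x = np.linalg.solve(A + 1e-9 * np.trace(A) / 3.0 * np.eye(3), b)
        if np.all(np.isfinite(x)):
            # reject wild solutions far from the edge
            mid = 0.5 * (va + vb)
            if np.linalg.norm(x - mid) < 4.0 * (np.linalg.norm(va - vb) + 1e-12):
                return x
    except np.linalg.LinAlgError:
        pass
    candidates = [va, vb, 0.5 * (va + vb)]
    errs = [float(np.append(c, 1.0) @ Q @ np.append(c, 1.0)) for c in candidates]
    return candidates[int(np.argmin(errs))]


def decimate(mesh: trimesh.Trimesh, target_face_fraction: float) -> trimesh.Trimesh:
    """Collapse edges until the face count reaches the requested fraction."""
    if not 0.0 < target_face_fraction <= 1.0:
        raise ValueError("target_face_fraction must be in (0, 1]")
    target = max(4, int(round(target_face_fraction * len(mesh.faces))))
    if target >= len(mesh.faces):
        return mesh.copy()

    V = mesh.vertices.copy()
    F = [list(f) for f in mesh.faces]
    alive_f = np.ones(len(F), dtype=bool)
    v2f: list[set] = [set() for _ in range(len(V))]
    for fi, f in enumerate(F):
        for v in f:
            v2f[v].add(fi)

    Q = [np.zeros((4, 4)) for _ in range(len(V))]
    for fi, f in enumerate(F):
        q = _face_quadric(V[f[0]], V[f[1]], V[f[2]])
        for v in f:
            Q[v] += q

    def neighbors(v):
        out = set()
        for fi in v2f[v]:
            if alive_f[fi]:
                out.update(F[fi])
        out.discard(v)
        return out

    def push_edge(heap, a, b, stamp):
        if a > b:
            a, b = b, a
        Qe = Q[a] + Q[b]
        x = _optimal_point(Qe, V[a], V[b])
        err = float(np.append(x, 1.0) @ Qe @ np.append(x, 1.0))
        heapq.heappush(heap, (err, stamp, a, b, tuple(x)))

    heap: list = []
    stamp = 0
    seen = set()
    for f in F:
        for a, b in ((f[0], f[1]), (f[1], f[2]), (f[2], f[0])):
            key = (min(a, b), max(a, b))
            if key not in seen:
                seen.add(key)
                push_edge(heap, a, b, stamp)
                stamp += 1

    n_faces = len(F)
    version = np.zeros(len(V), dtype=np.int64)

    while n_faces > target and heap:
        err, _, a, b, x = heapq.heappop(heap)
        if not (v2f[a] and v2f[b]):
            continue
        if not any(alive_f[fi] for fi in v2f[a]) or not any(alive_f[fi] for fi in v2f[b]):
            continue
        na = neighbors(a)
        if b not in na:
            continue
        nb = neighbors(b)
        shared_faces = [fi for fi in (v2f[a] & v2f[b]) if alive_f[fi]]
        if len(shared_faces) != 2:
            continue  # boundary or non-manifold edge: leave it
        opposite = set()
        for fi in shared_faces:
            opposite.update(set(F[fi]) - {a, b})
        if na & nb != opposite:
            continue  # link condition: collapse would pinch the surface
        x = np.asarray(x)
        # normal-flip check on surviving faces around a and b
        flip = False
        for fi in (v2f[a] | v2f[b]):
            if not alive_f[fi] or fi in shared_faces:
                continue
            f = F[fi]
            tri_old = [V[v] for v in f]
            tri_new = [x if v in (a, b) else V[v] for v in f]
            n_old = np.cross(tri_old[1] - tri_old[0], tri_old[2] - tri_old[0])
            n_new = np.cross(tri_new[1] - tri_new[0], tri_new[2] - tri_new[0])
            if np.dot(n_old, n_new) <= 1e-14:
                flip = True
                break
        if flip:
            continue

        # commit: merge b into a at x
        V[a] = x
        Q[a] = Q[a] + Q[b]
        for fi in shared_faces:
            alive_f[fi] = False
            n_faces -= 1
        for fi in list(v2f[b]):
            if not alive_f[fi]:
                continue
            F[fi] = [a if v == b else v for v in F[fi]]
            v2f[a].add(fi)
        v2f[b] = set()
        version[a] += 1
        for nb_v in neighbors(a):
            push_edge(heap, a, nb_v, stamp)
            stamp += 1

    faces = np.asarray([F[fi] for fi in range(len(F)) if alive_f[fi]], dtype=np.int64)
    out = trimesh.Trimesh(vertices=V, faces=faces, process=False)
    out.remove_unreferenced_vertices()
    return out
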