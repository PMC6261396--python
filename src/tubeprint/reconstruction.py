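"""Volume-to-surface reconstruction from transversal slice stacks.

Medical slice stacks arrive as grayscale transversal sections at a slice
step that is usually much coarser than the in-plane pixel spacing (3 mm is a
typical compromise for wide-area scans).  This module turns such a stack
into a clean triangulated surface: window thresholding, largest-component
extraction, iso-surfacing in world (mm) coordinates honouring anisotropic
spacing, and non-shrinking smoothing plus decimation.

Surface extraction is a marching-cubes iso-surfacer on the scalar grid; the
historical alternative of stacking per-slice contours produces the same
deliverable with more pathological cases.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import trimesh
from scipy import ndimage
from skimage import measure

from tubeprint.decimate import decimate
from tubeprint.geometry import GeometryError


@dataclass
class ImageVolume:
    """Axis-aligned scalar voxel grid.

    ``voxels[i, j, k]`` sits at world position ``origin + (i*dx, j*dy, k*dz)``;
    the last axis is the slice (z) axis, whose step ``dz`` may be much larger
    than the in-plane spacing.
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels)
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        self.spacing = tuple(float(s) for s in self.spacing)
        if self.voxels.ndim != 3 or min(self.voxels.shape) < 2:
            raise ValueError("volume must be 3D with at least 2 voxels per axis")
        if min(self.spacing) <= 0:
            raise ValueError("voxel spacing must be positive on all axes")

    @property
    def shape(self):
        return self.voxels.shape


@dataclass
class SegmentationMask:
    """Binary voxel grid congruent with its source :class:`ImageVolume`."""

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    origin: np.ndarray
    threshold: tuple[float, float] | None = None  # provenance

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels, dtype=bool)

    def as_volume(self) -> ImageVolume:
        return ImageVolume(self.voxels.astype(np.float32), self.spacing, self.origin)


def segment_threshold(vol: ImageVolume, lo: float, hi: float = np.inf,
                      keep_largest: bool = True) -> SegmentationMask:
    """Window threshold: keep voxels with lo <= value <= hi.

    With ``keep_largest`` only the largest 26-connected component survives,
    discarding speckle from noise and unrelated structures.
    """
    if lo > hi:
        raise ValueError(f"invalid window: lo={lo} > hi={hi}")
    mask = (vol.voxels >= lo) & (vol.voxels <= hi)
    if not mask.any():
        warnings.warn("threshold window selected no voxels; returning empty mask")
        return SegmentationMask(mask, vol.spacing, vol.origin, threshold=(lo, hi))
    if keep_largest:
        labels, n = ndimage.label(mask, structure=np.ones((3, 3, 3), dtype=int))
        if n > 1:
            counts = np.bincount(labels.ravel())
            counts[0] = 0
            mask = labels == int(np.argmax(counts))
    return SegmentationMask(mask, vol.spacing, vol.origin, threshold=(lo, hi))


def extract_surface(source: ImageVolume | SegmentationMask,
                    iso: float | None = None) -> trimesh.Trimesh:
    """Marching-cubes iso-surface in world millimetre coordinates.

    For a :class:`SegmentationMask` the level defaults to 0.5 on the 0/1
    grid.  Anisotropic slice steps are honoured through the grid spacing; no
    resampling is performed.  The result is watertight whenever the selected
    region does not touch the grid boundary.
    """
    if isinstance(source, SegmentationMask):
        grid = source.voxels.astype(np.float32)
        level = 0.5 if iso is None else float(iso)
        if not source.voxels.any():
            raise GeometryError("cannot extract a surface from an empty mask")
    else:
        grid = np.asarray(source.voxels, dtype=np.float32)
        if iso is None:
            raise ValueError("iso level is required for grayscale volumes")
        level = float(iso)
    if not grid.min() < level < grid.max():
        raise GeometryError(
            f"iso level {level} outside volume value range [{grid.min()}, {grid.max()}]")
    verts, faces, _, _ = measure.marching_cubes(grid, level=level, spacing=source.spacing)
    mesh = trimesh.Trimesh(vertices=verts + np.asarray(source.origin), faces=faces,
                           process=False)
    mesh.merge_vertices()
    trimesh.repair.fix_normals(mesh, multibody=True)
    if mesh.is_watertight and mesh.volume < 0:
        mesh.invert()
    return mesh


def smooth_and_decimate(mesh: trimesh.Trimesh, smoothing_iters: int = 10,
                        target_face_fraction: float = 1.0) -> trimesh.Trimesh:
    """Taubin (non-shrinking) smoothing followed by quadric decimation.

    Preserves watertightness; at default settings the enclosed volume changes
    by less than 2 %.  ``smoothing_iters=0`` with fraction 1.0 is the
    identity.
    """
    if not 0.0 < target_face_fraction <= 1.0:
        raise ValueError("target_face_fraction must be in (0, 1]")
    out = mesh.copy()
    if smoothing_iters > 0:
        # trimesh negates nu internally: this is the 0.5 / -0.53 pass pair
        out = trimesh.smoothing.filter_taubin(out, lamb=0.5, nu=0.53,
                                              iterations=int(smoothing_iters))
    if target_face_fraction < 1.0:
        out = decimate(out, target_face_fraction)
    return out
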