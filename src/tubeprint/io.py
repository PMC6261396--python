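"""File input/output: meshes, slice stacks, volumes, reports.

STL carries no units; everything read here is interpreted as millimetres
and that assumption is recorded in the returned object's metadata.
"""

from __future__ import annotations

import json
import re
from pathlib import Path

import numpy as np
import trimesh

from tubeprint.reconstruction import ImageVolume


def load_mesh(path) -> trimesh.Trimesh:
    """Read an STL/PLY/OBJ surface (binary or ASCII, auto-detected), in mm."""
    mesh = trimesh.load(str(path), force="mesh")
    out = trimesh.Trimesh(vertices=mesh.vertices, faces=mesh.faces, process=False)
    out.merge_vertices()
    out.metadata["units"] = "mm (assumed)"
    out.metadata["source"] = str(path)
    return out


def save_mesh(mesh: trimesh.Trimesh, path):
    mesh.export(str(path))


def load_slice_stack(directory) -> ImageVolume:
    """Read a numbered TIFF/PNG slice stack with a JSON metadata sidecar.

    The directory must contain images named with a trailing slice number
    (e.g. slice_000.tif) and a ``meta.json`` with ``spacing`` (dx, dy, dz in
    mm) and optional ``origin``.
    """
    directory = Path(directory)
    meta_path = directory / "meta.json"
    if not meta_path.exists():
        raise FileNotFoundError(f"missing metadata sidecar: {meta_path}")
    meta = json.loads(meta_path.read_text())
    files = [p for p in directory.iterdir()
             if p.suffix.lower() in (".tif", ".tiff", ".png")]

    def slice_number(p):
        m = re.search(r"(\d+)(?=\D*$)", p.stem)
        if m is None:
            raise ValueError(f"cannot find a slice number in {p.name}")
        return int(m.group(1))

    files.sort(key=slice_number)
    if not files:
        raise FileNotFoundError(f"no TIFF/PNG slices in {directory}")
    import imageio.v3 as iio
    slices = [np.asarray(iio.imread(p), dtype=np.float32) for p in files]
    vol = np.stack(slices, axis=-1)  # (row, col, slice) -> (x, y, z) grid axes
    return ImageVolume(vol, tuple(meta["spacing"]), meta.get("origin", (0.0, 0.0, 0.0)))


def save_slice_stack(vol: ImageVolume, directory, prefix: str = "slice"):
    """Write an ImageVolume as a numbered TIFF stack plus meta.json."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    import tifffile
    for k in range(vol.shape[2]):
        tifffile.imwrite(directory / f"{prefix}_{k:04d}.tif",
                         np.asarray(vol.voxels[:, :, k], dtype=np.float32))
    (directory / "meta.json").write_text(json.dumps(
        {"spacing": list(vol.spacing), "origin": vol.origin.tolist()}, indent=2))


def load_nrrd(path) -> ImageVolume:
    """Read an NRRD volume (via SimpleITK) into an ImageVolume."""
    import SimpleITK as sitk
    img = sitk.ReadImage(str(path))
    arr = sitk.GetArrayFromImage(img)          # (z, y, x)
    vox = np.transpose(arr, (2, 1, 0)).astype(np.float32)
    return ImageVolume(vox, tuple(img.GetSpacing()), np.asarray(img.GetOrigin()))


def load_volume(path) -> ImageVolume:
    """Dispatch on path: directory -> slice stack, .nrrd -> NRRD."""
    p = Path(path)
    if p.is_dir():
        return load_slice_stack(p)
    if p.suffix.lower() == ".nrrd":
        return load_nrrd(p)
    raise ValueError(f"unsupported volume input: {path}")


def write_json(obj, path, precision: int = 6):
    """Deterministic JSON: sorted keys, floats rounded to fixed precision."""

    def clean(x):
        if isinstance(x, dict):
            return {k: clean(v) for k, v in sorted(x.items())}
        if isinstance(x, (list, tuple)):
            return [clean(v) for v in x]
        if isinstance(x, (np.floating, float)):
            return round(float(x), precision)
        if isinstance(x, (np.integer,)):
            return int(x)
        if isinstance(x, np.ndarray):
            return clean(x.tolist())
        return x

    Path(path).write_text(json.dumps(clean(obj), indent=2, sort_keys=True) + "\n")
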