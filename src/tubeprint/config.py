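"""Pipeline configuration, machine presets, and plate-size checks."""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import trimesh
from shapely.geometry import MultiPoint


@dataclass(frozen=True)
class MachinePreset:
    """A desktop FFF machine profile (plate size in mm, slicing defaults)."""

    name: str
    plate: tuple[float, float, float]
    layer_height: float
    first_layer_height: float
    n_perimeters: int


# the two desktop systems the printed replicas were produced on
PRESETS = {
    "ds1": MachinePreset("ds1", (250.0, 220.0, 200.0), 0.15, 0.30, 3),
    "ds2": MachinePreset("ds2", (340.0, 340.0, 500.0), 0.16, 0.16, 4),
}


@dataclass
class PipelineConfig:
    """All tunable parameters of the end-to-end pipeline."""

    machine: str = "ds1"
    seed: int = 42
    # reconstruction
    threshold_lo: float = 50.0
    threshold_hi: float = float("inf")
    smoothing_iters: int = 10
    decimate_fraction: float = 1.0
    max_hole_edges: int = 100
    # centerline / segmentation
    voxel_pitch: float | None = None
    max_dev: float = 6.0
    # build planning
    critical_angle: float = 45.0
    angle_step: float = 4.0
    support_resolution: float = 1.5
    area_resolution: float = 0.25
    pin_radius: float = 2.0
    pin_height: float = 4.0
    pin_clearance: float = 0.1
    pin_count: int = 2
    shrinkage_scale: float = 1.0   # isotropic compensation hook (material-dependent)
    # slicing
    extrusion_width: float = 0.4
    infill_density: float = 0.15
    infill_pattern: str = "honeycomb"
    # deviation
    band: float = 1.0
    custom_band: tuple[float, float] | None = None
    keep_fraction: float = 0.19
    k_neighbors: int = 16
    trim_fraction: float = 0.9

    def __post_init__(self):
        if self.machine not in PRESETS:
            raise ValueError(f"unknown machine preset {self.machine!r}; "
                             f"choose from {sorted(PRESETS)}")
        if self.threshold_lo > self.threshold_hi:
            raise ValueError("threshold_lo must not exceed threshold_hi")
        if not 0.0 < self.decimate_fraction <= 1.0:
            raise ValueError("decimate_fraction must be in (0, 1]")
        if self.max_dev <= 0:
            raise ValueError("max_dev must be positive")
        if not 0.0 < self.critical_angle < 90.0:
            raise ValueError("critical_angle must be in (0, 90)")
        if self.support_resolution <= 0 or self.area_resolution <= 0:
            raise ValueError("resolutions must be positive")
        if self.pin_clearance < 0:
            raise ValueError("pin clearance must be non-negative")
        if not 0.0 <= self.infill_density <= 1.0:
            raise ValueError("infill density must be in [0, 1]")
        if not 0.0 < self.keep_fraction <= 1.0:
            raise ValueError("keep_fraction must be in (0, 1]")
        if not 0.0 < self.trim_fraction <= 1.0:
            raise ValueError("trim_fraction must be in (0, 1]")

    @property
    def preset(self) -> MachinePreset:
        return PRESETS[self.machine]

    @classmethod
    def from_json(cls, path) -> "PipelineConfig":
        data = json.loads(Path(path).read_text())
        if "custom_band" in data and data["custom_band"] is not None:
            data["custom_band"] = tuple(data["custom_band"])
        return cls(**data)

    def as_dict(self) -> dict:
        d = asdict(self)
        d["custom_band"] = list(self.custom_band) if self.custom_band else None
        return d


@dataclass
class PlateCheck:
    """Does each oriented part fit the machine's printing volume?"""

    results: list = field(default_factory=list)   # per part dicts

    @property
    def passed(self) -> bool:
        return all(r["fits"] for r in self.results)

    def add(self, name: str, mesh: trimesh.Trimesh, preset: MachinePreset):
        """Check one plate-placed part (build direction +z, free to rotate about z)."""
        v = np.asarray(mesh.vertices)
        height = float(v[:, 2].max() - v[:, 2].min())
        hull = MultiPoint(v[:, :2]).convex_hull
        rect = hull.minimum_rotated_rectangle
        coords = np.asarray(rect.exterior.coords)
        e1 = np.linalg.norm(coords[1] - coords[0])
        e2 = np.linalg.norm(coords[2] - coords[1])
        foot = sorted([float(e1), float(e2)])
        plate = sorted(preset.plate[:2])
        fits = (foot[0] <= plate[0] and foot[1] <= plate[1]
                and height <= preset.plate[2])
        self.results.append({
            "part": name,
            "footprint_mm": [round(f, 3) for f in foot],
            "height_mm": round(height, 3),
            "plate_mm": list(preset.plate),
            "fits": bool(fits),
        })
        return fits

    def as_dict(self):
        return {"passed": self.passed, "parts": self.results}
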