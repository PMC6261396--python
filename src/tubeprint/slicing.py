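"""Layer-wise manufacture simulation: slices, staircase error, tool paths.

FFF builds a part as a stack of planar layers; external surfaces not aligned
with the build direction show the staircase effect, whose cusp height per
face is layer_height * |cos theta| with theta the angle between the face
normal and the build direction.  This module slices a plate-placed mesh into
cross-section polygons (mid-layer sampling), computes the staircase metric,
and generates perimeter/infill paths with the printed parts' parameters as
defaults: 0.15 mm layers with a 0.30 mm first layer, 3 perimeters, and a
honeycomb infill at 15 % density, extruded in z.  Paths are geometry only —
no machine control.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import trimesh
from shapely.geometry import LineString, MultiPolygon, Polygon
from shapely.ops import unary_union

from tubeprint.geometry import GeometryError

log = logging.getLogger(__name__)

MIN_CONTOUR_AREA = 1e-4  # mm^2: degenerate tangential contours are dropped


@dataclass
class SliceStack:
    """Per-layer cross sections of a plate-placed solid."""

    z_levels: np.ndarray                 # mid-layer sampling heights (mm)
    layers: list                         # list of shapely (Multi)Polygon
    layer_height: float = 0.15
    first_layer_height: float = 0.30

    @property
    def n_layers(self) -> int:
        return len(self.z_levels)

    def layer_areas(self) -> np.ndarray:
        return np.array([p.area for p in self.layers])

    def layer_thicknesses(self) -> np.ndarray:
        t = np.full(len(self.z_levels), self.layer_height)
        if len(t):
            t[0] = self.first_layer_height
        return t

    def sliced_volume(self) -> float:
        """Volume of the stacked-slab approximation (area x thickness)."""
        return float(np.sum(self.layer_areas() * self.layer_thicknesses()))

    def to_json(self) -> str:
        return json.dumps({
            "layer_height": self.layer_height,
            "first_layer_height": self.first_layer_height,
            "n_layers": self.n_layers,
            "z_levels": [round(float(z), 6) for z in self.z_levels],
            "layer_areas": [round(float(a), 6) for a in self.layer_areas()],
        }, indent=2, sort_keys=True)

    def to_svg(self, path, layer_indices=None, scale: float = 1.0):
        """Write selected layer outlines into a simple SVG file."""
        idx = range(self.n_layers) if layer_indices is None else layer_indices
        parts = []
        for i in idx:
            geoms = getattr(self.layers[i], "geoms", [self.layers[i]])
            for g in geoms:
                for ring in [g.exterior, *g.interiors]:
                    pts = " ".join(f"{x*scale:.3f},{y*scale:.3f}" for x, y in ring.coords)
                    parts.append(f'<polyline points="{pts}" fill="none" stroke="black" stroke-width="0.1"/>')
        with open(path, "w") as fh:
            fh.write('<svg xmlns="http://www.w3.org/2000/svg">\n' + "\n".join(parts) + "\n</svg>\n")


@dataclass
class LayerPaths:
    """Extrusion paths of one layer: nested perimeter loops plus infill."""

    perimeters: list                     # list of coordinate arrays (closed loops)
    infill: list                         # list of coordinate arrays (polylines)
    extrusion_width: float = 0.4
    infill_region: Polygon | None = None

    def perimeter_length(self) -> float:
        return float(sum(LineString(p).length for p in self.perimeters))

    def infill_length(self) -> float:
        return float(sum(LineString(p).length for p in self.infill if len(p) > 1))


# --------------------------------------------------------------------------
# slicing
# --------------------------------------------------------------------------


def _rings_to_polygons(rings: list) -> MultiPolygon:
    """Assemble closed rings into polygons with holes by containment depth."""
    polys = []
    for r in rings:
        if len(r) < 4:
            continue
        p = Polygon(r)
        if not p.is_valid:
            p = p.buffer(0)
        if p.area > MIN_CONTOUR_AREA:
            polys.append(p)
    if not polys:
        return MultiPolygon([])
    depth = np.zeros(len(polys), dtype=int)
    for i, pi in enumerate(polys):
        for j, pj in enumerate(polys):
            if i != j and pj.area > pi.area and pj.contains(pi.representative_point()):
                depth[i] += 1
    out = []
    for i in np.flatnonzero(depth % 2 == 0):
        holes = [polys[j].exterior.coords for j in range(len(polys))
                 if depth[j] == depth[i] + 1 and polys[i].contains(polys[j].representative_point())]
        out.append(Polygon(polys[i].exterior.coords, holes=holes))
    return MultiPolygon(out)


def slice_mesh(mesh: trimesh.Trimesh, layer_height: float = 0.15,
               first_layer_height: float = 0.30) -> SliceStack:
    """Slice a watertight plate-placed mesh into mid-layer cross sections.

    The first layer occupies [0, first_layer_height] and is sampled at its
    center; subsequent layers of ``layer_height`` follow.  Mid-layer sampling
    (rather than bottom-plane sampling) is the convention here; layer counts
    differ by one between the two conventions.
    """
    if not mesh.is_watertight:
        raise GeometryError("slice_mesh requires a watertight mesh")
    zmin, zmax = mesh.bounds[0][2], mesh.bounds[1][2]
    if abs(zmin) > 1e-6:
        raise GeometryError("mesh must be placed on the plate (min z = 0)")
    levels = []
    z = first_layer_height / 2.0
    bottom = 0.0
    while bottom < zmax - 1e-12:
        levels.append(z)
        bottom = bottom + (first_layer_height if not levels[:-1] else layer_height)
        z = bottom + layer_height / 2.0
    layers = []
    for z in levels:
        sec = mesh.section(plane_origin=[0, 0, z], plane_normal=[0, 0, 1])
        if sec is None:
            layers.append(MultiPolygon([]))
            log.debug("empty section at z=%.4f", z)
            continue
        layers.append(_rings_to_polygons([np.asarray(r)[:, :2] for r in sec.discrete]))
    return SliceStack(z_levels=np.asarray(levels), layers=layers,
                      layer_height=layer_height, first_layer_height=first_layer_height)


# --------------------------------------------------------------------------
# staircase metric
# --------------------------------------------------------------------------


@dataclass
class StaircaseReport:
    per_face_cusp: np.ndarray
    mean: float                          # area-weighted
    max: float
    layer_height: float


def staircase_metric(mesh: trimesh.Trimesh, build_dir=(0, 0, 1.0),
                     layer_height: float = 0.15) -> StaircaseReport:
    """Cusp-height staircase error of the exterior surface.

    cusp = layer_height * |cos theta| per face; the summary is
    area-weighted over all faces.  Vertical walls score zero, horizontal
    faces the full layer height.
    """
    b = np.asarray(build_dir, dtype=float)
    nb = np.linalg.norm(b)
    if abs(nb - 1.0) > 1e-9:
        b = b / nb
    cusp = layer_height * np.abs(np.asarray(mesh.face_normals) @ b)
    areas = mesh.area_faces
    return StaircaseReport(per_face_cusp=cusp,
                           mean=float(np.average(cusp, weights=areas)),
                           max=float(cusp.max()),
                           layer_height=layer_height)


# --------------------------------------------------------------------------
# perimeters & infill
# --------------------------------------------------------------------------


def _hex_grid_segments(bounds, side: float):
    """Unique wall segments of a hexagonal tiling covering the bounds."""
    minx, miny, maxx, maxy = bounds
    dx = side * np.sqrt(3.0)          # horizontal center spacing
    dy = side * 1.5                   # vertical center spacing
    segs = set()

    def vkey(p):
        return (round(p[0], 6), round(p[1], 6))

    j0 = int(np.floor((miny - side) / dy)) - 1
    j1 = int(np.ceil((maxy + side) / dy)) + 1
    i0 = int(np.floor((minx - side) / dx)) - 1
    i1 = int(np.ceil((maxx + side) / dx)) + 1
    for j in range(j0, j1 + 1):
        for i in range(i0, i1 + 1):
            cx = i * dx + (dx / 2 if j % 2 else 0.0)
            cy = j * dy
            corners = [(cx + side * np.cos(np.pi / 6 + k * np.pi / 3),
                        cy + side * np.sin(np.pi / 6 + k * np.pi / 3)) for k in range(6)]
            for k in range(6):
                a, b = vkey(corners[k]), vkey(corners[(k + 1) % 6])
                segs.add((a, b) if a <= b else (b, a))
    return [np.array([a, b]) for a, b in segs]


def generate_layer_paths(layer, n_perimeters: int = 3,
                         extrusion_width: float = 0.4,
                         infill_density: float = 0.15,
                         pattern: str = "honeycomb") -> LayerPaths:
    """Perimeter loops and infill polylines for one layer's polygons.

    Perimeters are successive inward offsets of the contour at w/2, 3w/2, ...
    (regions too thin for the requested count simply get fewer loops).  The
    honeycomb infill is a hexagon-wall grid whose cell side is set so that
    walls of the extrusion width cover the requested density fraction:
    side = 2 w / (sqrt(3) * density).  Density 0 yields no infill; density 1
    a solid raster at the extrusion width.
    """
    if not 0.0 <= infill_density <= 1.0:
        raise ValueError("infill density must be within [0, 1]")
    geoms = list(getattr(layer, "geoms", [layer]))
    region = unary_union(geoms) if geoms else Polygon()
    w = extrusion_width
    perimeters = []
    for k in range(n_perimeters):
        inset = region.buffer(-(0.5 + k) * w)
        if inset.is_empty:
            log.debug("perimeter %d collapsed (region thinner than %g mm)",
                      k + 1, 2 * (0.5 + k) * w)
            break
        for g in getattr(inset, "geoms", [inset]):
            for ring in [g.exterior, *g.interiors]:
                perimeters.append(np.asarray(ring.coords))
    infill_region = region.buffer(-n_perimeters * w)
    infill: list = []
    if not infill_region.is_empty and infill_density > 0:
        if infill_density >= 1.0 or pattern == "solid":
            infill = _solid_raster(infill_region, w)
        elif pattern == "honeycomb":
            side = 2.0 * w / (np.sqrt(3.0) * infill_density)
            for seg in _hex_grid_segments(infill_region.bounds, side):
                inter = infill_region.intersection(LineString(seg))
                for g in getattr(inter, "geoms", [inter]):
                    if isinstance(g, LineString) and g.length > 1e-9:
                        infill.append(np.asarray(g.coords))
        else:
            raise ValueError(f"unknown infill pattern: {pattern}")
    return LayerPaths(perimeters=perimeters, infill=infill,
                      extrusion_width=w, infill_region=infill_region)


def _solid_raster(region, w):
    minx, miny, maxx, maxy = region.bounds
    out = []
    y = miny + w / 2
    while y < maxy:
        inter = region.intersection(LineString([(minx - 1, y), (maxx + 1, y)]))
        for g in getattr(inter, "geoms", [inter]):
            if isinstance(g, LineString) and g.length > 1e-9:
                out.append(np.asarray(g.coords))
        y += w
    return out


def infill_coverage_fraction(paths: LayerPaths) -> float:
    """Material-area fraction of the infill region covered by infill walls."""
    if paths.infill_region is None or paths.infill_region.is_empty:
        return 0.0
    lines = [LineString(p) for p in paths.infill if len(p) > 1]
    if not lines:
        return 0.0
    ribbon = unary_union([ln.buffer(paths.extrusion_width / 2, cap_style="flat")
                          for ln in lines])
    return float(ribbon.intersection(paths.infill_region).area / paths.infill_region.area)
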