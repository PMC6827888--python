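"""Synthetic generator for the complex multi-cell study domains.

Two families are produced:

* 8-cell columnar/pseudo-stratified epithelial sheets in eight variants
  (A–H), each differing from the baseline in exactly one biological
  feature: nuclear heating, nucleus position (pseudo-stratification),
  nucleus shape or location, or one-sided ("mitochondrial") heating.
* Voronoi-tessellated polygonal cell clusters with an interior nucleus per
  cell and a heat patch on a randomly chosen nucleus-adjacent side,
  emulating heating restricted to regions of mitochondrial clustering.
  These replace image-derived cell outlines with seeded random polygons of
  realistic size (~30–60 μm across, nuclei at ~8 % area fraction), keeping
  the analysis pipeline free of any image input.

Every scenario is fully determined by its parameters and RNG seed, carries
its gravity orientation (in-plane, −x₂), and round-trips through YAML.
Cells are hydraulically independent: no flow crosses cell boundaries.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import shapely
import yaml

from .errors import GeometryError, InvalidInputError
from .flow import ThermalBC
from .geometry import CellGeometry, HeatPatch, Membrane, Nucleus
from .meshing import Mesh, build_star_cell, merge_meshes
from .properties import celsius_to_kelvin

__all__ = [
    "CellScenario",
    "DomainScenario",
    "generate_epithelial_sheet",
    "generate_multicell_domain",
    "EPITHELIAL_VARIANTS",
]

EPITHELIAL_VARIANTS = tuple("ABCDEFGH")

_BASE_NUCLEUS_TEMP_C = 38.0
_NEUTRAL_TEMP_C = 37.0


@dataclass
class CellScenario:
    """One cell of a scenario: polygonal membrane, nucleus, thermal settings.

    ``polygon`` vertices are global coordinates (μm, CCW); ``patches`` are
    (name, theta_start, theta_end, temperature_C) arcs on the nucleus wall.
    """

    polygon: tuple
    nucleus_center: tuple
    nucleus_radii: tuple
    nucleus_angle: float = 0.0
    nucleus_temp_C: float = _BASE_NUCLEUS_TEMP_C
    patches: tuple = ()

    def geometry(self) -> CellGeometry:
        return CellGeometry(
            dimension=2,
            membrane=Membrane(kind="polygon", vertices=self.polygon, center=(0, 0)),
            nucleus=Nucleus(
                center=self.nucleus_center,
                radii=self.nucleus_radii,
                angle=self.nucleus_angle,
            ),
            heat_patches=tuple(
                HeatPatch(name=p[0], theta_start=p[1], theta_end=p[2])
                for p in self.patches
            ),
            gravity_direction=(0.0, -1.0),
        )


@dataclass
class DomainScenario:
    """A reproducible multi-cell domain with thermal assignment."""

    label: str
    cells: list
    seed: int
    membrane_temp_C: float = _NEUTRAL_TEMP_C
    gravity_direction: tuple = (0.0, -1.0)

    def build_mesh(self, target_edge_length: float = 0.8) -> Mesh:
        meshes = [
            build_star_cell(c.geometry(), target_edge_length, tag_suffix=f":{k}")
            for k, c in enumerate(self.cells)
        ]
        if len(meshes) == 1:
            mesh = meshes[0]
            mesh.element_region = np.zeros(len(mesh.cells), dtype=int)
            return mesh
        return merge_meshes(meshes)

    def thermal_bc(self) -> ThermalBC:
        """Wall temperatures for the whole sheet.

        The global nucleus temperature is overridden per cell (``w2:k``)
        and per heat patch, so mixed scenarios (uniformly heated nuclei in
        some cells, patch-only heating in others) are expressible.
        """
        overrides = {}
        for k, c in enumerate(self.cells):
            overrides[f"w2:{k}"] = float(celsius_to_kelvin(c.nucleus_temp_C))
            for p in c.patches:
                overrides[p[0]] = float(celsius_to_kelvin(p[3]))
        return ThermalBC(
            membrane_temperature=float(celsius_to_kelvin(self.membrane_temp_C)),
            nucleus_temperature=float(celsius_to_kelvin(self.membrane_temp_C)),
            patch_temperatures=overrides,
        )

    # -- serialization --------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "seed": int(self.seed),
            "membrane_temp_C": float(self.membrane_temp_C),
            "gravity_direction": [float(g) for g in self.gravity_direction],
            "cells": [
                {
                    "polygon": [[float(x), float(y)] for x, y in c.polygon],
                    "nucleus_center": [float(v) for v in c.nucleus_center],
                    "nucleus_radii": [float(v) for v in c.nucleus_radii],
                    "nucleus_angle": float(c.nucleus_angle),
                    "nucleus_temp_C": float(c.nucleus_temp_C),
                    "patches": [
                        [p[0], float(p[1]), float(p[2]), float(p[3])]
                        for p in c.patches
                    ],
                }
                for c in self.cells
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DomainScenario":
        cells = [
            CellScenario(
                polygon=tuple(tuple(v) for v in c["polygon"]),
                nucleus_center=tuple(c["nucleus_center"]),
                nucleus_radii=tuple(c["nucleus_radii"]),
                nucleus_angle=c.get("nucleus_angle", 0.0),
                nucleus_temp_C=c.get("nucleus_temp_C", _BASE_NUCLEUS_TEMP_C),
                patches=tuple(
                    (p[0], p[1], p[2], p[3]) for p in c.get("patches", [])
                ),
            )
            for c in d["cells"]
        ]
        return cls(
            label=d["label"],
            cells=cells,
            seed=int(d["seed"]),
            membrane_temp_C=d.get("membrane_temp_C", _NEUTRAL_TEMP_C),
            gravity_direction=tuple(d.get("gravity_direction", (0.0, -1.0))),
        )

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_yaml(cls, source) -> "DomainScenario":
        try:
            with open(source) as fh:
                data = yaml.safe_load(fh)
        except (OSError, TypeError):
            data = yaml.safe_load(source)
        return cls.from_dict(data)


# ----------------------------------------------------------------------------
# epithelial sheet variants
# ----------------------------------------------------------------------------


def _columnar_cells(
    n_cells: int,
    width: float,
    height: float,
    nucleus_y_fractions,
    nucleus_shape: str = "circle",
    nucleus_temp_C: float = _BASE_NUCLEUS_TEMP_C,
    one_sided_heating: bool = False,
) -> list:
    r = math.sqrt(0.08 * width * height / math.pi)
    cells = []
    for k in range(n_cells):
        x0 = k * width
        poly = (
            (x0, 0.0),
            (x0 + width, 0.0),
            (x0 + width, height),
            (x0, height),
        )
        cy = nucleus_y_fractions[k] * height
        if nucleus_shape == "circle":
            radii, angle = (r,), 0.0
        else:  # vertically elongated ellipse of equal area
            radii, angle = (r / 1.35, 1.35 * r), 0.0
        patches = ()
        temp = nucleus_temp_C
        if one_sided_heating:
            # heating restricted to the left-facing half of the nucleus wall
            patches = ((f"mito{k}", math.pi / 2, 3 * math.pi / 2, _BASE_NUCLEUS_TEMP_C),)
            temp = _NEUTRAL_TEMP_C
        cells.append(
            CellScenario(
                polygon=poly,
                nucleus_center=(x0 + width / 2.0, cy),
                nucleus_radii=radii,
                nucleus_angle=angle,
                nucleus_temp_C=temp,
                patches=patches,
            )
        )
    return cells


def generate_epithelial_sheet(
    variant: str,
    seed: int = 0,
    n_cells: int = 8,
    cell_width: float = 10.0,
    cell_height: float = 25.0,
) -> DomainScenario:
    """Generate one of the 8 epithelial-sheet variants.

    A  baseline columnar sheet (uniform basal nuclei, nuclei at 38 °C)
    B  increased nuclear heating (39 °C)
    C  pseudo-stratified: alternating low/high nuclei
    D  pseudo-stratified: three-level staggered nuclei
    E  pseudo-stratified: seeded random nucleus heights
    F  altered nucleus shape (vertically elongated ellipses, equal area)
    G  altered nucleus location (apical instead of basal)
    H  uneven heating (one side of each nucleus heated, rest neutral)

    Each variant differs from baseline A in exactly the named attribute.
    """
    variant = str(variant).upper()
    if variant not in EPITHELIAL_VARIANTS:
        raise InvalidInputError(
            f"unknown variant {variant!r}; expected one of {EPITHELIAL_VARIANTS}"
        )
    base_frac = [0.3] * n_cells
    kwargs = dict(nucleus_y_fractions=base_frac)
    if variant == "B":
        kwargs["nucleus_temp_C"] = _BASE_NUCLEUS_TEMP_C + 1.0
    elif variant == "C":
        kwargs["nucleus_y_fractions"] = [
            0.25 if k % 2 == 0 else 0.55 for k in range(n_cells)
        ]
    elif variant == "D":
        kwargs["nucleus_y_fractions"] = [
            (0.2, 0.4, 0.6)[k % 3] for k in range(n_cells)
        ]
    elif variant == "E":
        rng = np.random.default_rng(seed)
        kwargs["nucleus_y_fractions"] = list(rng.uniform(0.2, 0.7, size=n_cells))
    elif variant == "F":
        kwargs["nucleus_shape"] = "ellipse"
    elif variant == "G":
        kwargs["nucleus_y_fractions"] = [0.7] * n_cells
    elif variant == "H":
        kwargs["one_sided_heating"] = True
    cells = _columnar_cells(n_cells, cell_width, cell_height, **kwargs)
    return DomainScenario(label=f"epithelial_{variant}", cells=cells, seed=seed)


# ----------------------------------------------------------------------------
# Voronoi multicell domains
# ----------------------------------------------------------------------------


def generate_multicell_domain(
    n_cells: int,
    seed: int = 0,
    mito_patch_fraction: float = 0.5,
    mean_cell_diameter: float = 45.0,
    nucleus_area_fraction: float = 0.08,
    patch_temp_C: float = _BASE_NUCLEUS_TEMP_C,
) -> DomainScenario:
    """Seeded random polygonal cell cluster with nucleus-adjacent heating.

    Cell outlines are a Lloyd-relaxed Voronoi tessellation of a square
    region, clipped and slightly shrunk so neighbouring cells do not share
    walls.  Each cell gets an interior circular nucleus scaled to
    ``nucleus_area_fraction`` of its area, with a heat patch covering
    ``mito_patch_fraction`` of the nucleus wall on a randomly chosen side;
    the remainder of the nucleus wall stays neutral, so only the
    "mitochondrial" patch drives flow.
    """
    if n_cells < 1:
        raise InvalidInputError("n_cells must be >= 1")
    if not (0.0 < mito_patch_fraction <= 1.0):
        raise InvalidInputError("mito_patch_fraction must be in (0, 1]")
    rng = np.random.default_rng(seed)
    side = mean_cell_diameter * math.sqrt(n_cells)
    pts = rng.uniform(0.12 * side, 0.88 * side, size=(n_cells, 2))
    box = shapely.box(0.0, 0.0, side, side)
    for _ in range(3):  # Lloyd relaxation evens the cell sizes
        polys = _clipped_voronoi(pts, box, side)
        pts = np.array([p.centroid.coords[0] for p in polys])
    polys = _clipped_voronoi(pts, box, side)

    cells = []
    for k, poly in enumerate(polys):
        poly = poly.buffer(-0.04 * mean_cell_diameter, join_style="mitre")
        if poly.is_empty or poly.geom_type != "Polygon":
            raise GeometryError(f"degenerate cell polygon for cell {k}")
        centroid = np.array(poly.centroid.coords[0])
        clearance = shapely.distance(poly.exterior, poly.centroid)
        r_target = math.sqrt(nucleus_area_fraction * poly.area / math.pi)
        r = min(r_target, 0.65 * clearance)
        if r < 0.3 * r_target:
            raise GeometryError(
                f"nucleus cannot fit in cell {k} (clearance {clearance:.2f} μm)"
            )
        phi0 = float(rng.uniform(0.0, 2 * math.pi))
        half = math.pi * mito_patch_fraction
        verts = tuple(poly.exterior.coords)[:-1]
        if _polygon_area(verts) < 0:
            verts = verts[::-1]
        cells.append(
            CellScenario(
                polygon=verts,
                nucleus_center=tuple(centroid),
                nucleus_radii=(r,),
                nucleus_temp_C=_NEUTRAL_TEMP_C,
                patches=((f"mito{k}", phi0 - half, phi0 + half, patch_temp_C),),
            )
        )
    return DomainScenario(label=f"multicell_{n_cells}", cells=cells, seed=seed)


def _polygon_area(verts) -> float:
    v = np.asarray(verts)
    x, y = v[:, 0], v[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def _clipped_voronoi(pts: np.ndarray, box, side: float) -> list:
    """Voronoi cells of ``pts`` clipped to ``box`` (always bounded)."""
    from scipy.spatial import Voronoi

    if len(pts) == 1:
        return [box]
    # mirror points across the box edges to bound every cell
    mirrored = [pts]
    for axis, bound in ((0, 0.0), (0, side), (1, 0.0), (1, side)):
        m = pts.copy()
        m[:, axis] = 2 * bound - m[:, axis]
        mirrored.append(m)
    vor = Voronoi(np.vstack(mirrored))
    polys = []
    for i in range(len(pts)):
        region = vor.regions[vor.point_region[i]]
        if -1 in region or not region:
            raise GeometryError("unbounded Voronoi cell after mirroring")
        poly = shapely.Polygon(vor.vertices[region]).intersection(box)
        if poly.geom_type != "Polygon" or poly.is_empty:
            raise GeometryError("degenerate Voronoi cell")
        polys.append(poly)
    return polys
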