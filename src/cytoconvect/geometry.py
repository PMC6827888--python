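"""Geometric descriptors for cell-scale computational domains.

Domains are a fluid region between an outer membrane wall (tag ``w1``) and
the wall of a hollow nucleus (tag ``w2``), optionally with named heat
patches on the nucleus-adjacent boundary.  Coordinates are micrometres
throughout; conversion to SI happens once at solver entry.

The gravity direction is part of the geometry: cells are simulated in a
fixed orientation, with gravity along −x₃ in 3-D and −x₂ in 2-D by default.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import GeometryError, InvalidInputError

__all__ = [
    "Nucleus",
    "Membrane",
    "HeatPatch",
    "CellGeometry",
    "nucleus_radius_for_fraction",
    "nucleus_volume_fraction",
]


def nucleus_radius_for_fraction(R: float, f: float, dimension: int = 3) -> float:
    """Nuclear radius giving a nucleus-to-cell volume fraction ``f``.

    For concentric spheres (or discs in 2-D) the nucleus occupies a fraction
    ``(r/R)**dimension`` of the total cell volume, so ``r = R * f**(1/dim)``.
    A 10 μm cell with an 8 % nuclear volume fraction gives r ≈ 4.3 μm.
    """
    if not (0.0 < f <= 1.0):
        raise InvalidInputError(f"volume fraction must be in (0, 1], got {f!r}")
    if R <= 0:
        raise InvalidInputError(f"cell radius must be > 0, got {R!r}")
    if dimension not in (2, 3):
        raise InvalidInputError("dimension must be 2 or 3")
    return R * f ** (1.0 / dimension)


def nucleus_volume_fraction(R: float, r: float, dimension: int = 3) -> float:
    """Inverse of :func:`nucleus_radius_for_fraction`: fraction = (r/R)**dim."""
    if R <= 0 or r <= 0:
        raise InvalidInputError("radii must be > 0")
    return (r / R) ** dimension


@dataclass(frozen=True)
class Nucleus:
    """Spherical/elliptical nucleus descriptor.

    ``radii`` are semi-axes in μm; a single value (or equal values) gives a
    circle/sphere.  ``angle`` rotates the ellipse in the 2-D plane (radians).
    """

    center: tuple
    radii: tuple
    angle: float = 0.0

    def __post_init__(self):
        object.__setattr__(self, "center", tuple(float(c) for c in self.center))
        radii = self.radii if hasattr(self.radii, "__len__") else (self.radii,)
        radii = tuple(float(r) for r in radii)
        if len(radii) == 1:
            radii = radii * len(self.center)
        if len(radii) != len(self.center):
            raise InvalidInputError("nucleus radii/center dimension mismatch")
        if any(r <= 0 for r in radii):
            raise InvalidInputError("nucleus semi-axes must be > 0")
        object.__setattr__(self, "radii", radii)

    @property
    def dimension(self) -> int:
        return len(self.center)

    def support_radius(self, direction: np.ndarray) -> np.ndarray:
        """Distance from the nucleus center to its wall along unit ``direction``.

        2-D ellipses may be rotated by ``angle``; 3-D nuclei are spheroids
        aligned with the axes (the rotation angle applies in the x1-x2 plane).
        """
        e = np.atleast_2d(np.asarray(direction, dtype=float))
        if self.dimension == 2:
            a, b = self.radii
            ca, sa = math.cos(self.angle), math.sin(self.angle)
            # rotate direction into the ellipse frame
            ex = e[:, 0] * ca + e[:, 1] * sa
            ey = -e[:, 0] * sa + e[:, 1] * ca
            r = 1.0 / np.sqrt((ex / a) ** 2 + (ey / b) ** 2)
        else:
            a, b, c = self.radii
            ca, sa = math.cos(self.angle), math.sin(self.angle)
            ex = e[:, 0] * ca + e[:, 1] * sa
            ey = -e[:, 0] * sa + e[:, 1] * ca
            ez = e[:, 2]
            r = 1.0 / np.sqrt((ex / a) ** 2 + (ey / b) ** 2 + (ez / c) ** 2)
        return r if np.ndim(direction) > 1 else float(r[0])

    def signed_distance(self, points: np.ndarray) -> np.ndarray:
        """Approximate signed distance to the nucleus wall (> 0 outside).

        Exact for circles/spheres; a normalized implicit-function estimate
        for ellipses, adequate for particle reflection.
        """
        x = np.atleast_2d(np.asarray(points, dtype=float)) - np.asarray(self.center)
        if len(set(self.radii)) == 1:
            return np.linalg.norm(x, axis=1) - self.radii[0]
        rr = np.asarray(self.radii)
        if self.dimension == 2 and self.angle != 0.0:
            ca, sa = math.cos(self.angle), math.sin(self.angle)
            x = np.column_stack([x[:, 0] * ca + x[:, 1] * sa,
                                 -x[:, 0] * sa + x[:, 1] * ca])
        q = np.linalg.norm(x / rr, axis=1)
        return (q - 1.0) * rr.min()


@dataclass(frozen=True)
class Membrane:
    """Outer cell wall: a sphere/disc of radius ``radius`` centered at
    ``center``, or a simple polygon given by ``vertices`` (2-D only)."""

    kind: str = "sphere"  # "sphere" (disc in 2-D) or "polygon"
    radius: float | None = None
    center: tuple = (0.0, 0.0, 0.0)
    vertices: tuple | None = None  # ((x, y), ...) CCW, polygon only

    def __post_init__(self):
        if self.kind not in ("sphere", "polygon"):
            raise InvalidInputError(f"unknown membrane kind {self.kind!r}")
        if self.kind == "sphere":
            if self.radius is None or self.radius <= 0:
                raise InvalidInputError("spherical membrane needs radius > 0")
        else:
            if self.vertices is None or len(self.vertices) < 3:
                raise InvalidInputError("polygon membrane needs >= 3 vertices")
            object.__setattr__(
                self, "vertices", tuple(tuple(map(float, v)) for v in self.vertices)
            )
        object.__setattr__(self, "center", tuple(float(c) for c in self.center))


@dataclass(frozen=True)
class HeatPatch:
    """Named subset of the nucleus wall where an elevated temperature is imposed.

    In 2-D the patch is the arc of nucleus-wall angles within
    [``theta_start``, ``theta_end``] (radians, measured about the nucleus
    center, counter-clockwise from +x1, interval may wrap).  In 3-D it is the
    spherical cap of wall directions within ``theta_end`` radians of the axis
    whose polar angle in the x1–x3 plane is ``theta_start``.
    """

    name: str
    theta_start: float
    theta_end: float


@dataclass(frozen=True)
class CellGeometry:
    """Complete description of one fluid domain (μm units)."""

    dimension: int
    membrane: Membrane
    nucleus: Nucleus
    heat_patches: tuple = ()
    gravity_direction: tuple | None = None

    def __post_init__(self):
        if self.dimension not in (2, 3):
            raise InvalidInputError("dimension must be 2 or 3")
        gdir = self.gravity_direction
        if gdir is None:
            gdir = (0.0, -1.0) if self.dimension == 2 else (0.0, 0.0, -1.0)
        g = np.asarray(gdir, dtype=float)
        if g.shape != (self.dimension,) or not np.linalg.norm(g) > 0:
            raise InvalidInputError("gravity_direction must be a nonzero d-vector")
        object.__setattr__(
            self, "gravity_direction", tuple(g / np.linalg.norm(g))
        )
        object.__setattr__(self, "heat_patches", tuple(self.heat_patches))
        self._validate()

    @property
    def vertical_axis(self) -> np.ndarray:
        """Unit vector pointing 'up' (opposite to gravity)."""
        return -np.asarray(self.gravity_direction)

    def membrane_ray_distance(self, origin: np.ndarray, directions: np.ndarray) -> np.ndarray:
        """Distance from ``origin`` to the membrane along unit ``directions``.

        Requires the membrane to be star-shaped as seen from ``origin``
        (always true for spheres and convex polygons with an interior origin).
        """
        e = np.atleast_2d(np.asarray(directions, dtype=float))
        o = np.asarray(origin, dtype=float)
        if self.membrane.kind == "sphere":
            c = o - np.asarray(self.membrane.center[: self.dimension])
            R = self.membrane.radius
            ce = e @ c
            disc = ce**2 + R**2 - c @ c
            if np.any(disc <= 0):
                raise GeometryError("ray origin outside the membrane")
            t = -ce + np.sqrt(disc)
        else:
            verts = np.asarray(self.membrane.vertices)
            p, q = verts, np.roll(verts, -1, axis=0)
            t = np.full(len(e), np.inf)
            for pi, qi in zip(p, q):
                d = qi - pi
                # solve o + t e = pi + s d
                denom = e[:, 0] * (-d[1]) - e[:, 1] * (-d[0])
                w = pi - o
                with np.errstate(divide="ignore", invalid="ignore"):
                    ti = (w[0] * (-d[1]) - w[1] * (-d[0])) / denom
                    si = (e[:, 0] * w[1] - e[:, 1] * w[0]) / denom
                ok = np.isfinite(ti) & (ti > 1e-12) & (si >= -1e-12) & (si <= 1 + 1e-12)
                t = np.where(ok & (ti < t), ti, t)
            if not np.all(np.isfinite(t)):
                raise GeometryError("ray from nucleus center missed the membrane")
        return t if np.ndim(directions) > 1 else float(t[0])

    def membrane_signed_distance(self, points: np.ndarray) -> np.ndarray:
        """Signed distance to the membrane (> 0 outside the cell)."""
        x = np.atleast_2d(np.asarray(points, dtype=float))
        if self.membrane.kind == "sphere":
            c = np.asarray(self.membrane.center[: self.dimension])
            return np.linalg.norm(x - c, axis=1) - self.membrane.radius
        import shapely

        poly = shapely.Polygon(self.membrane.vertices)
        pts = shapely.points(x[:, 0], x[:, 1])
        d = shapely.distance(pts, poly.exterior)
        inside = shapely.contains(poly, pts)
        return np.where(inside, -d, d)

    def _validate(self):
        nuc = self.nucleus
        if nuc.dimension != self.dimension:
            raise GeometryError("nucleus dimension does not match domain dimension")
        # sample directions, require strict clearance between the walls
        n = 720 if self.dimension == 2 else 2000
        if self.dimension == 2:
            th = np.linspace(0, 2 * np.pi, n, endpoint=False)
            e = np.column_stack([np.cos(th), np.sin(th)])
        else:
            rng = np.random.default_rng(0)
            e = rng.normal(size=(n, 3))
            e /= np.linalg.norm(e, axis=1, keepdims=True)
        r_in = nuc.support_radius(e)
        r_out = self.membrane_ray_distance(np.asarray(nuc.center), e)
        if np.any(r_out - r_in <= 1e-9):
            raise GeometryError(
                "nucleus touches or crosses the membrane "
                f"(min clearance {float(np.min(r_out - r_in)):.3g} μm)"
            )


def spherical_cell_geometry(
    R: float = 10.0,
    r_nucleus: float = 4.3,
    offset: tuple | float = 2.0,
    dimension: int = 3,
    heat_patches: tuple = (),
) -> CellGeometry:
    """Convenience constructor for the default eccentric spherical cell.

    ``offset`` displaces the nucleus from the cell center along +x1 (scalar)
    or by an explicit vector (μm).  Defaults give the 10 μm cell with a
    4.3 μm nucleus (8 % volume fraction) shifted 2 μm off-center.
    """
    if np.isscalar(offset):
        off = np.zeros(dimension)
        off[0] = float(offset)
    else:
        off = np.asarray(offset, dtype=float)
        if off.shape != (dimension,):
            raise InvalidInputError("offset vector dimension mismatch")
    membrane = Membrane(kind="sphere", radius=float(R), center=(0.0,) * dimension)
    nucleus = Nucleus(center=tuple(off), radii=(float(r_nucleus),))
    return CellGeometry(
        dimension=dimension,
        membrane=membrane,
        nucleus=nucleus,
        heat_patches=tuple(heat_patches),
    )
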