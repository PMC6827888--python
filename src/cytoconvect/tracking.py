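"""Lagrangian particle tracking: advection by the computed flow plus
Brownian motion.

Particles are inertialess (overdamped): at cell scales the particle
Reynolds and Stokes numbers are vanishingly small, so each step is the
Euler–Maruyama update

    x_{k+1} = x_k + u(x_k) Δt + √(2 D Δt) ξ_k   (+ optional Stokes settling)

with ξ standard normal per component.  The optional settling velocity
(ρ_p − ρ_f) g d_p² / (18 μ) is ≈ 4.5e-4 μm/s for a 0.1 μm particle of
density 1050 kg/m³ — under 2 % of the ΔT = 1 °C flow speed — and is off by
default.  Wall collisions are handled by specular reflection off the
analytic wall surfaces, which conserves particles in the closed domain.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .errors import InvalidInputError
from .flow import UM, FlowSolution
from .meshing import Mesh

__all__ = [
    "ParticleSpec",
    "Trajectory",
    "FlowInterpolator",
    "track_particle",
    "track_ensemble",
    "ensemble_msd",
    "classify_regime",
]


@dataclass(frozen=True)
class ParticleSpec:
    """Physical description of a tracked particle.

    ``diffusivity`` is the translational diffusion coefficient in μm²/s;
    ``start`` the release position in μm (default (−2, −2), a point inside
    the default 2-D cell on the downwelling side of the nucleus).
    """

    density: float = 1050.0          # kg m⁻³
    diameter: float = 0.1            # μm
    diffusivity: float = 0.01        # μm² s⁻¹
    start: tuple = (-2.0, -2.0)
    settling: bool = False

    def __post_init__(self):
        if self.diameter <= 0:
            raise InvalidInputError("particle diameter must be > 0")
        if self.diffusivity < 0:
            raise InvalidInputError("diffusivity must be >= 0")

    def settling_velocity_um_s(self, props) -> float:
        """Stokes settling speed (positive = along gravity), μm/s."""
        d_si = self.diameter * UM
        dv = (self.density - props.reference_density) * props.gravity * d_si**2
        return dv / (18.0 * props.dynamic_viscosity) / UM


@dataclass
class Trajectory:
    """Time-stamped particle path (μm) with its generating seed."""

    positions: np.ndarray   # (n_steps+1, d), μm
    timestamps: np.ndarray  # (n_steps+1,), s
    seed: int
    spec: ParticleSpec

    @property
    def dt(self) -> float:
        return float(self.timestamps[1] - self.timestamps[0])

    def to_frame(self) -> pd.DataFrame:
        cols = {f"x{i+1}": self.positions[:, i] for i in range(self.positions.shape[1])}
        return pd.DataFrame({"t": self.timestamps, **cols}).assign(seed=self.seed)


class FlowInterpolator:
    """Element-local linear interpolation of the P1 velocity field.

    Candidate elements come from a k-d tree over element centroids; the
    containing element is identified by barycentric coordinates.  Query
    points marginally outside the mesh (the polygonal boundary is inscribed
    in the analytic wall) fall back to the nearest element with clipped
    barycentric weights, which degrades gracefully to the no-slip value.
    """

    def __init__(self, mesh: Mesh, u_um_s: np.ndarray, k: int = 12):
        self.mesh = mesh
        self.u = u_um_s
        self.k = min(k, len(mesh.cells))
        pts = mesh.points
        d = mesh.dim
        cells = mesh.cells
        self.tree = cKDTree(pts[cells].mean(axis=1))
        p0 = pts[cells[:, 0]]
        E = pts[cells[:, 1:]] - p0[:, None, :]
        self.Einv = np.linalg.inv(np.transpose(E, (0, 2, 1)))  # (ne, d, d)
        self.p0 = p0
        self.cells = cells
        self.d = d

    def barycentric(self, elems: np.ndarray, x: np.ndarray) -> np.ndarray:
        """(n, d+1) barycentric coordinates of points x in elements elems."""
        lam = np.einsum("nij,nj->ni", self.Einv[elems], x - self.p0[elems])
        lam0 = 1.0 - lam.sum(axis=1, keepdims=True)
        return np.concatenate([lam0, lam], axis=1)

    def velocity(self, x: np.ndarray) -> np.ndarray:
        """Velocity (μm/s) at points ``x`` (n, d) in μm."""
        x = np.atleast_2d(np.asarray(x, dtype=float))
        _, cand = self.tree.query(x, k=self.k)
        cand = np.atleast_2d(cand)
        n = len(x)
        best_lam = np.full((n, self.d + 1), -np.inf)
        best_el = cand[:, 0].copy()
        found = np.zeros(n, dtype=bool)
        for j in range(cand.shape[1]):
            todo = ~found
            if not np.any(todo):
                break
            el = cand[todo, j]
            lam = self.barycentric(el, x[todo])
            ok = lam.min(axis=1) >= -1e-9
            # keep the best (least-outside) candidate as fallback
            idx_todo = np.where(todo)[0]
            better = lam.min(axis=1) > best_lam[idx_todo].min(axis=1)
            best_lam[idx_todo[better]] = lam[better]
            best_el[idx_todo[better]] = el[better]
            found[idx_todo[ok]] = True
        lam = np.clip(best_lam, 0.0, None)
        lam /= lam.sum(axis=1, keepdims=True)
        u_nodes = self.u[self.cells[best_el]]          # (n, d+1, d)
        return np.einsum("ni,nid->nd", lam, u_nodes)

    def inside(self, x: np.ndarray, tol: float = 1e-9) -> np.ndarray:
        x = np.atleast_2d(np.asarray(x, dtype=float))
        _, cand = self.tree.query(x, k=self.k)
        cand = np.atleast_2d(cand)
        ok = np.zeros(len(x), dtype=bool)
        for j in range(cand.shape[1]):
            lam = self.barycentric(cand[:, j], x)
            ok |= lam.min(axis=1) >= -tol
        return ok


def _reflect_walls(geom, x: np.ndarray) -> np.ndarray:
    """Specular reflection of points across the analytic wall surfaces."""
    x = x.copy()
    for _ in range(8):
        moved = False
        # membrane (sphere or polygon)
        dm = geom.membrane_signed_distance(x)
        out = dm > 0
        if np.any(out):
            moved = True
            if geom.membrane.kind == "sphere":
                c = np.asarray(geom.membrane.center[: geom.dimension])
                v = x[out] - c
                r = np.linalg.norm(v, axis=1, keepdims=True)
                x[out] = c + (2.0 * geom.membrane.radius - r) * v / r
            else:
                import shapely

                ext = shapely.Polygon(geom.membrane.vertices).exterior
                pts = shapely.points(x[out][:, 0], x[out][:, 1])
                proj = np.array(
                    [shapely.ops.nearest_points(p, ext)[1].coords[0] for p in pts]
                )
                x[out] = 2.0 * proj - x[out]
        # nucleus
        dn = geom.nucleus.signed_distance(x)
        ins = dn < 0
        if np.any(ins):
            moved = True
            c = np.asarray(geom.nucleus.center)
            rr = np.asarray(geom.nucleus.radii)
            v = (x[ins] - c) / rr          # ellipse -> unit sphere space
            r = np.linalg.norm(v, axis=1, keepdims=True)
            r = np.where(r > 0, r, 1.0)
            x[ins] = c + ((2.0 - r) * v / r) * rr
        if not moved:
            return x
    # pathological corner: clamp midway between the walls along the nucleus ray
    bad = (geom.membrane_signed_distance(x) > 0) | (geom.nucleus.signed_distance(x) < 0)
    if np.any(bad):
        c = np.asarray(geom.nucleus.center)
        v = x[bad] - c
        e = v / np.linalg.norm(v, axis=1, keepdims=True)
        r_in = np.atleast_1d(geom.nucleus.support_radius(e))
        r_out = np.atleast_1d(geom.membrane_ray_distance(c, e))
        x[bad] = c + (0.5 * (r_in + r_out))[:, None] * e
    return x


def track_ensemble(
    flow: FlowSolution,
    spec: ParticleSpec,
    dt: float,
    n_steps: int,
    seeds,
) -> list:
    """Track one particle per seed (vectorized across the ensemble).

    Returns a list of :class:`Trajectory`, bit-reproducible per seed: each
    particle consumes an independent ``numpy.random.default_rng(seed)``
    stream, so an ensemble member equals the corresponding single-particle
    :func:`track_particle` run.
    """
    seeds = [int(s) for s in np.atleast_1d(seeds)]
    mesh = flow.mesh
    d = mesh.dim
    if dt <= 0:
        raise InvalidInputError("dt must be > 0")
    start = np.asarray(spec.start, dtype=float)
    if start.shape != (d,):
        raise InvalidInputError(f"start position must have dimension {d}")
    interp = FlowInterpolator(mesh, flow.velocity_um_s)
    geom = mesh.geometry
    if geom is not None:
        if (
            geom.membrane_signed_distance(start[None, :])[0] >= 0
            or geom.nucleus.signed_distance(start[None, :])[0] <= 0
        ):
            raise InvalidInputError(f"start position {tuple(start)} outside fluid")
    elif not interp.inside(start[None, :])[0]:
        raise InvalidInputError(f"start position {tuple(start)} outside fluid")
    # a single advective or diffusive step must not exceed the domain size
    domain_diam = float(np.ptp(mesh.points, axis=0).max())
    step_scale = flow.max_speed_um_s * dt + 4.0 * math.sqrt(2 * spec.diffusivity * dt)
    if step_scale > domain_diam:
        raise InvalidInputError(
            f"dt={dt} allows steps (~{step_scale:.3g} μm) larger than the domain"
        )
    v_settle = np.zeros(d)
    if spec.settling:
        g_dir = (
            np.asarray(geom.gravity_direction) if geom is not None
            else -np.eye(d)[-1]
        )
        v_settle = spec.settling_velocity_um_s(flow.props) * g_dir

    rngs = [np.random.default_rng(s) for s in seeds]
    m = len(seeds)
    x = np.tile(start, (m, 1))
    sigma = math.sqrt(2.0 * spec.diffusivity * dt)
    traj = np.empty((n_steps + 1, m, d))
    traj[0] = x
    for k in range(n_steps):
        u = interp.velocity(x)
        xi = np.stack([r.standard_normal(d) for r in rngs])
        x = x + (u + v_settle) * dt + sigma * xi
        if geom is not None:
            x = _reflect_walls(geom, x)
        else:
            ok = interp.inside(x)
            x[~ok] = traj[k][~ok]  # no analytic walls: reject the step
        traj[k + 1] = x
    t = np.arange(n_steps + 1) * dt
    return [
        Trajectory(positions=traj[:, i].copy(), timestamps=t.copy(), seed=seeds[i],
                   spec=spec)
        for i in range(m)
    ]


def track_particle(
    flow: FlowSolution,
    spec: ParticleSpec,
    dt: float,
    n_steps: int,
    seed: int,
) -> Trajectory:
    """Track a single particle; same seed → identical trajectory."""
    return track_ensemble(flow, spec, dt, n_steps, [seed])[0]


def ensemble_msd(trajectories) -> pd.DataFrame:
    """Mean squared displacement ⟨|x(t) − x(0)|²⟩ across an ensemble.

    Requires at least one trajectory with identical timestamps; returns a
    DataFrame with columns ``t`` and ``msd`` (μm²).
    """
    trajectories = list(trajectories)
    if not trajectories:
        raise InvalidInputError("empty trajectory collection")
    t0 = trajectories[0].timestamps
    for tr in trajectories[1:]:
        if tr.timestamps.shape != t0.shape or not np.allclose(tr.timestamps, t0):
            raise InvalidInputError("trajectories have mismatched timestamps")
    disp2 = np.stack(
        [np.sum((tr.positions - tr.positions[0]) ** 2, axis=1) for tr in trajectories]
    )
    return pd.DataFrame({"t": t0, "msd": disp2.mean(axis=0)})


def classify_regime(trajectories, flow: FlowSolution, factor: float = 2.0) -> str:
    """Label an ensemble convection-dominated, diffusion-dominated or mixed.

    The advective signal is the ensemble-mean drift distance accumulated
    along the local flow direction, Σ Δx·û(x); the diffusive scale is
    √(2 d D t) for the run duration t.  Ratios above ``factor`` are
    convection-dominated, below ``1/factor`` diffusion-dominated, else mixed.
    """
    trajectories = list(trajectories)
    if not trajectories:
        raise InvalidInputError("empty trajectory collection")
    interp = FlowInterpolator(flow.mesh, flow.velocity_um_s)
    drifts = []
    for tr in trajectories:
        u = interp.velocity(tr.positions[:-1])
        norm = np.linalg.norm(u, axis=1)
        uhat = np.where(norm[:, None] > 0, u / np.where(norm[:, None] > 0, norm[:, None], 1.0), 0.0)
        steps = np.diff(tr.positions, axis=0)
        drifts.append(float(np.sum(np.einsum("nd,nd->n", steps, uhat))))
    drift = float(np.mean(drifts))
    d = flow.mesh.dim
    D = trajectories[0].spec.diffusivity
    t_total = float(trajectories[0].timestamps[-1] - trajectories[0].timestamps[0])
    diffusive = math.sqrt(2.0 * d * D * t_total)
    if diffusive == 0.0:
        return "convection-dominated" if drift > 0 else "mixed"
    ratio = drift / diffusive
    if ratio > factor:
        return "convection-dominated"
    if ratio < 1.0 / factor:
        return "diffusion-dominated"
    return "mixed"
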