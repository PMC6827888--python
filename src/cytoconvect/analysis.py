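"""Derived feasibility analyses: velocity–temperature sweeps and Péclet maps.

The central question these answer: what wall-temperature difference ΔT and
molecular diffusivity D allow buoyant convection (speed u*) to rival
diffusion at cell scale, i.e. Pe = u* L / D ≳ 1?
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConvergenceError, InvalidInputError
from .flow import FlowSolution, SolverOptions, ThermalBC, solve_flow
from .meshing import Mesh, build_spherical_cell
from .properties import FluidProperties, celsius_to_kelvin

__all__ = [
    "SweepResult",
    "PecletMap",
    "max_vertical_velocities",
    "sweep_nuclear_temperature",
    "peclet_map",
    "net_plane_flux",
]


def max_vertical_velocities(solution: FlowSolution) -> tuple[float, float]:
    """Maximum upwelling and downwelling speeds (both positive, μm/s).

    Upwelling is the global max of the vertical velocity component (against
    gravity); downwelling the magnitude of its most negative value.
    """
    w = solution.vertical_velocity_um_s()
    return float(max(w.max(), 0.0)), float(max(-w.min(), 0.0))


@dataclass
class SweepResult:
    """Velocity maxima vs imposed nuclear-wall temperature.

    ``table`` columns: nuclear_temp_C, delta_T_C, w_up_um_s, w_down_um_s,
    converged.  Failed solves are recorded, not dropped.
    """

    table: pd.DataFrame
    membrane_temp_C: float

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    @property
    def delta_T(self) -> np.ndarray:
        return self.table["delta_T_C"].to_numpy()

    @property
    def w_up(self) -> np.ndarray:
        return self.table["w_up_um_s"].to_numpy()


def sweep_nuclear_temperature(
    temps_celsius,
    geometry,
    props: FluidProperties,
    membrane_temp_celsius: float = 37.0,
    options: SolverOptions | None = None,
    mesh: Mesh | None = None,
    **mesh_kwargs,
) -> SweepResult:
    """One converged flow solve per imposed nuclear temperature (°C).

    The membrane is held at ``membrane_temp_celsius``.  The mesh is built
    once from ``geometry`` (or supplied directly) and reused across the
    sweep.  Non-converged solves yield a row with ``converged = False`` and
    NaN velocities.
    """
    temps = [float(t) for t in np.atleast_1d(temps_celsius)]
    if not temps:
        raise InvalidInputError("empty temperature list")
    if mesh is None:
        mesh = build_spherical_cell(geometry, **mesh_kwargs)
    rows = []
    for t_nuc in temps:
        bc = ThermalBC(
            membrane_temperature=float(celsius_to_kelvin(membrane_temp_celsius)),
            nucleus_temperature=float(celsius_to_kelvin(t_nuc)),
        )
        try:
            sol = solve_flow(mesh, props, bc, options)
            w_up, w_down = max_vertical_velocities(sol)
            rows.append((t_nuc, t_nuc - membrane_temp_celsius, w_up, w_down, True))
        except ConvergenceError:
            rows.append((t_nuc, t_nuc - membrane_temp_celsius, np.nan, np.nan, False))
    table = pd.DataFrame(
        rows,
        columns=["nuclear_temp_C", "delta_T_C", "w_up_um_s", "w_down_um_s", "converged"],
    )
    return SweepResult(table=table, membrane_temp_C=membrane_temp_celsius)


@dataclass
class PecletMap:
    """Pe = u*(ΔT) · L / D tabulated over a (ΔT, D) grid.

    ``pe[i, j]`` corresponds to ``delta_T[i]`` and ``D_grid[j]``;
    ``feasible`` is the boolean mask Pe > 1 where convection can dominate.
    """

    delta_T: np.ndarray        # °C
    D_grid: np.ndarray         # μm²/s
    u_star: np.ndarray         # μm/s, one per ΔT
    pe: np.ndarray             # (n_dT, n_D)
    length_scale_um: float

    @property
    def feasible(self) -> np.ndarray:
        return self.pe > 1.0

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.pe,
            index=pd.Index(self.delta_T, name="delta_T_C"),
            columns=pd.Index(self.D_grid, name="D_um2_s"),
        )

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path)

    def plot(self, ax=None, path=None):
        """Optional heatmap (ΔT vs D, log-scaled Pe color, Pe = 1 contour)."""
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(6, 4.5))
        mesh = ax.pcolormesh(
            self.D_grid,
            self.delta_T,
            np.log10(self.pe),
            shading="nearest",
            cmap="viridis",
        )
        ax.contour(self.D_grid, self.delta_T, self.pe, levels=[1.0], colors="r")
        ax.set_xscale("log")
        ax.set_xlabel("diffusion coefficient D (μm²/s)")
        ax.set_ylabel("ΔT (°C)")
        ax.figure.colorbar(mesh, ax=ax, label="log10 Pe")
        if path is not None:
            ax.figure.savefig(path, dpi=150, bbox_inches="tight")
        return ax


def peclet_map(sweep: SweepResult, D_grid=None, L: float = 20.0) -> PecletMap:
    """Build the Péclet feasibility map from a velocity sweep.

    ``u*`` for each ΔT is the sweep's maximum upwelling velocity; ``L``
    defaults to 20 μm (the cell diameter); ``D_grid`` defaults to 30
    log-spaced values over 0.01–100 μm²/s, a conservative span of
    cytoplasmic diffusivities.
    """
    if L <= 0:
        raise InvalidInputError("length scale L must be > 0")
    if D_grid is None:
        D_grid = np.logspace(-2, 2, 30)
    D_grid = np.asarray(D_grid, dtype=float)
    if D_grid.size == 0:
        raise InvalidInputError("empty diffusivity grid")
    if np.any(D_grid <= 0):
        raise InvalidInputError("diffusivities must be > 0")
    ok = sweep.table["converged"].to_numpy()
    dT = sweep.delta_T[ok]
    u_star = sweep.w_up[ok]
    pe = u_star[:, None] * L / D_grid[None, :]
    return PecletMap(delta_T=dT, D_grid=D_grid, u_star=u_star, pe=pe,
                     length_scale_um=L)


def net_plane_flux(solution: FlowSolution, height: float | None = None) -> tuple[float, float]:
    """Net and gross vertical volume flux through a horizontal plane (μm³/s).

    The plane is ``height`` μm along the vertical axis (default: through the
    nucleus center).  For the closed circulations here the net flux vanishes
    to discretization tolerance while the gross flux ∫|w| measures the
    circulation strength.  Works in 2-D (flux per unit depth, μm²/s) and 3-D.
    """
    mesh = solution.mesh
    up = solution.up_axis
    z = mesh.points @ up
    if height is None:
        if mesh.geometry is None:
            raise InvalidInputError("plane height required for meshes without geometry")
        height = float(np.asarray(mesh.geometry.nucleus.center) @ up)
    # if mesh nodes lie exactly on the plane (structured meshes do this),
    # nudge the plane a fraction of an element off the degenerate line
    h_min = float(mesh.element_sizes().min())
    if np.any(np.abs(z - height) < 1e-9 * max(1.0, abs(height))):
        height = height + 0.25 * h_min
    w = solution.vertical_velocity_um_s()
    zc = z[mesh.cells]                          # (ne, d+1)
    wc = w[mesh.cells]
    net = 0.0
    gross = 0.0
    side = zc - height
    crossing = np.where((side.min(axis=1) < 0) & (side.max(axis=1) > 0))[0]
    pts = mesh.points[mesh.cells]
    for e in crossing:
        s = side[e]
        verts = pts[e]
        vals = wc[e]
        cut_pts, cut_vals = [], []
        nv = len(s)
        for i in range(nv):
            for j in range(i + 1, nv):
                if s[i] * s[j] < 0:
                    lam = s[i] / (s[i] - s[j])
                    cut_pts.append(verts[i] + lam * (verts[j] - verts[i]))
                    cut_vals.append(vals[i] + lam * (vals[j] - vals[i]))
        if len(cut_pts) < mesh.dim:
            continue
        cut_pts = np.asarray(cut_pts)
        cut_vals = np.asarray(cut_vals)
        if mesh.dim == 2:
            # segment: integrate linear w over its length
            length = np.linalg.norm(cut_pts[1] - cut_pts[0])
            net += length * cut_vals.mean()
            gross += length * np.abs(cut_vals).mean()
        else:
            # polygon (3 or 4 vertices): fan-triangulate about the centroid
            order = _order_polygon(cut_pts, up)
            cut_pts, cut_vals = cut_pts[order], cut_vals[order]
            c = cut_pts.mean(axis=0)
            cv = cut_vals.mean()
            m = len(cut_pts)
            for i in range(m):
                a, b = cut_pts[i], cut_pts[(i + 1) % m]
                va, vb = cut_vals[i], cut_vals[(i + 1) % m]
                area = 0.5 * np.linalg.norm(np.cross(a - c, b - c))
                net += area * (va + vb + cv) / 3.0
                gross += area * abs(va + vb + cv) / 3.0
    return float(net), float(gross)


def _order_polygon(pts: np.ndarray, normal: np.ndarray) -> np.ndarray:
    c = pts.mean(axis=0)
    ref = pts[0] - c
    ref /= np.linalg.norm(ref)
    t2 = np.cross(normal, ref)
    ang = np.arctan2((pts - c) @ t2, (pts - c) @ ref)
    return np.argsort(ang)
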