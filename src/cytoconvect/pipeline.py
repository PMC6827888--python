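"""Reproducible end-to-end runs: config in, artifacts + manifest out.

A :class:`RunConfig` (YAML-serializable) names a geometry or synthetic
scenario, fluid-property overrides, wall temperatures in °C, solver
settings and the analyses to run.  :func:`run_pipeline` executes the
requested stages in order — mesh, flow solve, then any of concentration
transport, particle tracking, temperature sweep and Péclet map — writing
VTU/CSV artifacts and a JSON manifest with a checksum per file.  Interface
units are °C and μm; conversion to SI happens once inside the solvers.
"""

from __future__ import annotations

import hashlib
import json
import traceback
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as cio
from .analysis import max_vertical_velocities, peclet_map, sweep_nuclear_temperature
from .domains import DomainScenario
from .errors import ConfigurationError
from .flow import FlowSolution, SolverOptions, ThermalBC, solve_flow
from .geometry import spherical_cell_geometry
from .meshing import Mesh, build_spherical_cell
from .properties import FluidProperties, celsius_to_kelvin, kelvin_to_celsius
from .tracking import ParticleSpec, track_ensemble
from .transport import ConcentrationField, solve_concentration

__all__ = ["RunConfig", "run_pipeline", "write_fields"]


@dataclass
class RunConfig:
    """Declarative description of one pipeline run (presentation units)."""

    geometry: dict = field(
        default_factory=lambda: {
            "kind": "spherical",
            "dimension": 2,
            "R": 10.0,
            "r_nucleus": 4.3,
            "offset": 2.0,
        }
    )
    resolution: dict = field(default_factory=dict)
    fluid: dict = field(default_factory=dict)
    thermal: dict = field(
        default_factory=lambda: {"membrane_C": 37.0, "nucleus_C": 38.0}
    )
    solver: dict = field(default_factory=dict)
    analyses: dict = field(default_factory=dict)
    output_dir: str = "cytoconvect_run"
    seed: int = 0

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    def to_dict(self) -> dict:
        return {
            "geometry": self.geometry,
            "resolution": self.resolution,
            "fluid": self.fluid,
            "thermal": self.thermal,
            "solver": self.solver,
            "analyses": self.analyses,
            "output_dir": self.output_dir,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        return cls(**{k: d[k] for k in d if k in cls.__dataclass_fields__})

    @classmethod
    def from_yaml(cls, source) -> "RunConfig":
        try:
            data = yaml.safe_load(Path(source).read_text())
        except (OSError, TypeError):
            data = yaml.safe_load(source)
        return cls.from_dict(data or {})


def _build_domain(cfg: RunConfig):
    g = cfg.geometry
    kind = g.get("kind", "spherical")
    if kind == "spherical":
        geom = spherical_cell_geometry(
            R=g.get("R", 10.0),
            r_nucleus=g.get("r_nucleus", 4.3),
            offset=g.get("offset", 2.0),
            dimension=g.get("dimension", 2),
        )
        mesh = build_spherical_cell(geom, **cfg.resolution)
        bc = ThermalBC(
            membrane_temperature=float(
                celsius_to_kelvin(cfg.thermal.get("membrane_C", 37.0))
            ),
            nucleus_temperature=float(
                celsius_to_kelvin(cfg.thermal.get("nucleus_C", 38.0))
            ),
            patch_temperatures={
                k: float(celsius_to_kelvin(v))
                for k, v in cfg.thermal.get("patches_C", {}).items()
            },
        )
        return geom, mesh, bc
    if kind == "scenario":
        scenario = DomainScenario.from_dict(g["scenario"])
        mesh = scenario.build_mesh(**cfg.resolution)
        return scenario, mesh, scenario.thermal_bc()
    raise ConfigurationError(f"unknown geometry kind {kind!r}")


def write_fields(
    solution: FlowSolution,
    concentration: ConcentrationField | None,
    mesh: Mesh,
    path,
) -> list:
    """Write solution fields as VTU plus a CSV summary; returns the paths.

    Point data: velocity (μm/s), temperature (°C), pressure (Pa) and, when
    given, the normalized concentration.
    """
    path = Path(path)
    if path.suffix != ".vtu":
        path = path.with_suffix(".vtu")
    path.parent.mkdir(parents=True, exist_ok=True)
    data = {
        "velocity_um_s": solution.velocity_um_s,
        "temperature_C": np.asarray(kelvin_to_celsius(solution.T)),
        "pressure_Pa": solution.p,
    }
    if concentration is not None:
        data["concentration"] = concentration.c
    cio.write_vtu(path, mesh, data)
    w_up, w_down = max_vertical_velocities(solution)
    summary = pd.DataFrame(
        [
            {
                "max_speed_um_s": solution.max_speed_um_s,
                "max_upwelling_um_s": w_up,
                "max_downwelling_um_s": w_down,
                "iterations": solution.iterations,
                **{f"residual_{k}": v for k, v in solution.residuals.items()},
            }
        ]
    )
    csv_path = path.with_name(path.stem + "_summary.csv")
    summary.to_csv(csv_path, index=False)
    return [path, csv_path]


def _sha256(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages; returns (and writes) the run manifest.

    Stage failures are recorded in the manifest (with the partial artifacts
    preserved) rather than raised, so a long sweep is never lost to one bad
    configuration.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"config": config.to_dict(), "artifacts": {}, "metrics": {},
                "failures": {}, "log": []}
    config.to_yaml(out / "config.yaml")
    props = (
        FluidProperties(**{**FluidProperties().to_dict(), **config.fluid})
        if config.fluid
        else FluidProperties()
    )
    options = SolverOptions(**config.solver) if config.solver else SolverOptions()
    solution = None
    mesh = None
    try:
        domain, mesh, bc = _build_domain(config)
        cio.write_msh(out / "mesh.msh", mesh)
        solution = solve_flow(mesh, props, bc, options)
        manifest["log"].append(
            {
                "stage": "flow",
                "iterations": solution.iterations,
                "residual_history": [
                    {k: float(v) for k, v in r.items()}
                    for r in solution.residual_history
                ],
            }
        )
        w_up, w_down = max_vertical_velocities(solution)
        manifest["metrics"]["max_upwelling_um_s"] = w_up
        manifest["metrics"]["max_downwelling_um_s"] = w_down
        manifest["metrics"]["max_speed_um_s"] = solution.max_speed_um_s
    except Exception as exc:  # noqa: BLE001 — manifest records the failure
        manifest["failures"]["flow"] = "".join(
            traceback.format_exception_only(exc)
        ).strip()

    concentration = None
    analyses = config.analyses
    if solution is not None and "concentration" in analyses:
        try:
            spec = analyses["concentration"]
            concentration = solve_concentration(
                solution, mesh, D=spec.get("D", 0.1),
                source_wall=spec.get("source_wall", "w1"),
            )
        except Exception as exc:  # noqa: BLE001
            manifest["failures"]["concentration"] = "".join(
                traceback.format_exception_only(exc)
            ).strip()
    if solution is not None:
        files = write_fields(solution, concentration, mesh, out / "fields.vtu")

    if solution is not None and "tracking" in analyses:
        try:
            t = analyses["tracking"]
            spec = ParticleSpec(
                diffusivity=t.get("D", 0.01),
                start=tuple(t.get("start", (-2.0, -2.0))),
                settling=t.get("settling", False),
            )
            seeds = t.get("seeds")
            if seeds is None:
                seeds = [config.seed + i for i in range(t.get("n_particles", 10))]
            trajectories = track_ensemble(
                solution, spec, dt=t.get("dt", 0.01),
                n_steps=t.get("n_steps", 1000), seeds=seeds,
            )
            frames = pd.concat([tr.to_frame() for tr in trajectories])
            frames.to_csv(out / "trajectories.csv", index=False)
        except Exception as exc:  # noqa: BLE001
            manifest["failures"]["tracking"] = "".join(
                traceback.format_exception_only(exc)
            ).strip()

    if "sweep_temps_C" in analyses and mesh is not None:
        try:
            sweep = sweep_nuclear_temperature(
                analyses["sweep_temps_C"],
                geometry=None,
                props=props,
                membrane_temp_celsius=config.thermal.get("membrane_C", 37.0),
                options=options,
                mesh=mesh,
            )
            sweep.to_csv(out / "sweep.csv")
            manifest["metrics"]["sweep_rows"] = int(len(sweep.table))
            if "peclet" in analyses:
                pk = analyses["peclet"]
                pmap = peclet_map(
                    sweep,
                    D_grid=pk.get("D_grid"),
                    L=pk.get("L", 20.0),
                )
                pmap.to_csv(out / "peclet_map.csv")
                manifest["metrics"]["peclet_max"] = float(pmap.pe.max())
        except Exception as exc:  # noqa: BLE001
            manifest["failures"]["sweep"] = "".join(
                traceback.format_exception_only(exc)
            ).strip()

    for f in sorted(out.iterdir()):
        if f.name != "manifest.json" and f.is_file():
            manifest["artifacts"][f.name] = _sha256(f)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
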