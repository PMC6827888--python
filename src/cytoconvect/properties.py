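"""Physical constants, equation of state and dimensionless groups.

The working fluid is cytosol, modelled with the bulk thermodynamic
properties of water at 37 °C (the cytoplasm is ~70 % water and its
viscosity is close to that of pure water).  Density varies linearly
with temperature through the thermal-expansion coefficient,

    rho(T) = rho0 * (1 - beta * (T - T0)),

which is the only place temperature feeds back on the mechanics
(buoyancy).  All quantities are stored in SI units; temperatures are
Kelvin internally and degrees Celsius only at the presentation layer.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import yaml

from .errors import InvalidInputError

__all__ = [
    "FluidProperties",
    "ReferenceScales",
    "DimensionlessNumbers",
    "density_from_temperature",
    "derived_properties",
    "dimensionless_numbers",
    "celsius_to_kelvin",
    "kelvin_to_celsius",
]

#: 0 °C in Kelvin.
ZERO_CELSIUS = 273.15


def celsius_to_kelvin(t_celsius):
    """Convert °C to K (array-friendly)."""
    return np.asarray(t_celsius, dtype=float) + ZERO_CELSIUS


def kelvin_to_celsius(t_kelvin):
    """Convert K to °C (array-friendly)."""
    return np.asarray(t_kelvin, dtype=float) - ZERO_CELSIUS


@dataclass(frozen=True)
class FluidProperties:
    """Bulk thermophysical properties of the cytosolic fluid (SI units).

    Defaults are water-like values at a reference temperature of 37 °C
    (310.15 K).  ``specific_heat`` is stored in J kg⁻¹ K⁻¹ (4178, i.e. the
    tabulated 4.178 kJ kg⁻¹ K⁻¹ converted once on entry) so that the derived
    thermal diffusivity ``kappa = lam / (rho0 * Cp)`` carries no hidden unit
    factor.

    Parameters
    ----------
    kinematic_viscosity : float
        ν, m² s⁻¹.
    reference_density : float
        ρ0, kg m⁻³, density at the reference temperature.
    thermal_expansion : float
        β, K⁻¹, volumetric thermal-expansion coefficient.
    specific_heat : float
        Cp, J kg⁻¹ K⁻¹.
    thermal_conductivity : float
        λ, W m⁻¹ K⁻¹.
    gravity : float
        g, m s⁻², magnitude of gravitational acceleration.
    reference_temperature : float
        T0, K, temperature at which the density equals ``reference_density``.
    """

    kinematic_viscosity: float = 0.6959e-6
    reference_density: float = 993.38
    thermal_expansion: float = 0.361e-3
    specific_heat: float = 4178.0
    thermal_conductivity: float = 0.6252
    gravity: float = 9.81
    reference_temperature: float = 310.15

    def __post_init__(self):
        for name in (
            "kinematic_viscosity",
            "reference_density",
            "thermal_expansion",
            "specific_heat",
            "thermal_conductivity",
            "reference_temperature",
        ):
            value = getattr(self, name)
            if not math.isfinite(value) or value <= 0.0:
                raise InvalidInputError(
                    f"FluidProperties.{name} must be finite and > 0, got {value!r}"
                )
        # g = 0 is allowed: switching gravity off isolates pure conduction,
        # a useful verification limit.
        if not math.isfinite(self.gravity) or self.gravity < 0.0:
            raise InvalidInputError(
                f"FluidProperties.gravity must be finite and >= 0, got {self.gravity!r}"
            )

    @property
    def dynamic_viscosity(self) -> float:
        """μ = ρ0 ν (Pa s)."""
        return self.reference_density * self.kinematic_viscosity

    @property
    def thermal_diffusivity(self) -> float:
        """κ = λ / (ρ0 Cp) (m² s⁻¹)."""
        return self.thermal_conductivity / (
            self.reference_density * self.specific_heat
        )

    def density(self, temperature):
        """Equation of state ρ(T); see :func:`density_from_temperature`."""
        return density_from_temperature(self, temperature)

    def to_dict(self) -> dict:
        return {
            "kinematic_viscosity": self.kinematic_viscosity,
            "reference_density": self.reference_density,
            "thermal_expansion": self.thermal_expansion,
            "specific_heat": self.specific_heat,
            "thermal_conductivity": self.thermal_conductivity,
            "gravity": self.gravity,
            "reference_temperature": self.reference_temperature,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FluidProperties":
        return cls(**{k: float(v) for k, v in d.items()})

    @classmethod
    def from_yaml(cls, path) -> "FluidProperties":
        """Load properties from a YAML file; missing keys fall back to defaults."""
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if "fluid_properties" in data:
            data = data["fluid_properties"]
        defaults = cls().to_dict()
        defaults.update({k: float(v) for k, v in data.items()})
        return cls(**defaults)


@dataclass(frozen=True)
class ReferenceScales:
    """Characteristic scales used to form dimensionless groups.

    ``length_scale`` L (m) is typically the cell diameter or radius;
    ``temperature_deviation`` θ (K) the imposed wall-temperature difference;
    ``reference_velocity`` U (m s⁻¹) a representative flow speed, usually
    taken from simulation output.
    """

    length_scale: float
    temperature_deviation: float = 0.0
    reference_velocity: float = 0.0

    def __post_init__(self):
        if not (math.isfinite(self.length_scale) and self.length_scale > 0):
            raise InvalidInputError("length_scale must be finite and > 0")
        if not (math.isfinite(self.temperature_deviation) and self.temperature_deviation >= 0):
            raise InvalidInputError("temperature_deviation must be finite and >= 0")


@dataclass(frozen=True)
class DimensionlessNumbers:
    """The four groups characterising the flow regime.

    Re = u* L / ν   (inertia vs viscosity)
    Ga = g L³ / ν²  (gravity vs viscosity)
    Ra = u* L / κ   (thermal advection vs thermal diffusion)
    Pe = u* L / D   (advective vs diffusive mass transport)

    Ra is implemented in the velocity-based (thermal-Péclet) form: the flow
    here is driven by imposed wall temperatures, not characterised by a
    buoyancy-velocity closure, so u* is an observed speed.
    """

    reynolds: float
    galilei: float
    rayleigh: float
    peclet: float


def density_from_temperature(props: FluidProperties, temperature):
    """Linearised equation of state ρ = ρ0 (1 − β (T − T0)).

    Parameters
    ----------
    props : FluidProperties
    temperature : float or ndarray
        Absolute temperature in Kelvin.

    Returns
    -------
    float or ndarray
        Density in kg m⁻³; strictly decreasing in T.
    """
    T = np.asarray(temperature, dtype=float)
    if not np.all(np.isfinite(T)):
        raise InvalidInputError("temperature must be finite (Kelvin)")
    rho = props.reference_density * (
        1.0 - props.thermal_expansion * (T - props.reference_temperature)
    )
    return float(rho) if np.isscalar(temperature) else rho


def derived_properties(props: FluidProperties) -> tuple[float, float]:
    """Return (dynamic viscosity μ, thermal diffusivity κ)."""
    return props.dynamic_viscosity, props.thermal_diffusivity


def dimensionless_numbers(
    props: FluidProperties,
    scales: ReferenceScales,
    u_star: float,
    D: float,
) -> DimensionlessNumbers:
    """Compute Re, Ga, Ra and Pe from one consistent set of scales.

    Parameters
    ----------
    props : FluidProperties
    scales : ReferenceScales
        Supplies the length scale L (m).
    u_star : float
        Representative flow speed (m s⁻¹), ≥ 0.
    D : float
        Molecular diffusivity (m² s⁻¹), > 0 (Pe is undefined at D = 0).
    """
    if not (math.isfinite(u_star) and u_star >= 0):
        raise InvalidInputError("u_star must be finite and >= 0")
    if not (math.isfinite(D) and D > 0):
        raise InvalidInputError("diffusivity D must be finite and > 0 (Pe undefined)")
    L = scales.length_scale
    nu = props.kinematic_viscosity
    kappa = props.thermal_diffusivity
    return DimensionlessNumbers(
        reynolds=u_star * L / nu,
        galilei=props.gravity * L**3 / nu**2,
        rayleigh=u_star * L / kappa,
        peclet=u_star * L / D,
    )
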