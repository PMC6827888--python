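"""Physical constants, equation of state and dimensionless groups."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import cytoconvect as cc
from cytoconvect.errors import InvalidInputError


class TestEquationOfState:
    @pytest.mark.parametrize(
        "T,expected",
        [
            (310.15, 993.38),      # reference temperature returns rho0
            (311.15, 993.02139),   # rho0 * (1 - beta * 1)
            (323.15, 988.71807),   # rho0 * (1 - beta * 13)
        ],
    )
    def test_density_values(self, props, T, expected):
        assert cc.density_from_temperature(props, T) == pytest.approx(expected, abs=5e-5)

    def test_density_rejects_non_finite_temperature(self, props):
        for bad in (float("nan"), float("inf")):
            with pytest.raises(InvalidInputError):
                cc.density_from_temperature(props, bad)

    @given(T=st.floats(min_value=273.0, max_value=373.0))
    @settings(deadline=None)
    def test_density_affine_with_slope_minus_rho0_beta(self, T):
        props = cc.FluidProperties()
        dT = 0.5
        slope = (
            cc.density_from_temperature(props, T + dT)
            - cc.density_from_temperature(props, T)
        ) / dT
        expected = -props.reference_density * props.thermal_expansion
        assert slope == pytest.approx(expected, rel=1e-9)


class TestDerivedProperties:
    def test_table_defaults(self, props):
        mu, kappa = cc.derived_properties(props)
        assert mu == pytest.approx(6.913e-4, rel=1e-3)       # rho0 * nu
        assert kappa == pytest.approx(1.5064e-7, rel=1e-3)   # lam / (rho0 Cp)

    def test_kappa_exact_identity(self, props):
        mu, kappa = cc.derived_properties(props)
        assert kappa == props.thermal_conductivity / (
            props.reference_density * props.specific_heat
        )

    def test_doubling_conductivity_doubles_diffusivity(self, props):
        doubled = cc.FluidProperties(
            **{**props.to_dict(), "thermal_conductivity": 2 * props.thermal_conductivity}
        )
        assert doubled.thermal_diffusivity == pytest.approx(
            2 * props.thermal_diffusivity
        )

    def test_invalid_fields_rejected(self):
        with pytest.raises(InvalidInputError):
            cc.FluidProperties(reference_density=0.0)
        with pytest.raises(InvalidInputError):
            cc.FluidProperties(specific_heat=-1.0)
        with pytest.raises(InvalidInputError):
            cc.FluidProperties(gravity=-9.81)


class TestDimensionlessNumbers:
    def test_peclet_unity_example(self, props):
        # u* = 0.01 μm/s, L = 10 μm, D = 0.1 μm²/s -> Pe = 1
        nums = cc.dimensionless_numbers(
            props, cc.ReferenceScales(length_scale=10e-6), u_star=0.01e-6, D=0.1e-12
        )
        assert nums.peclet == pytest.approx(1.0)

    def test_zero_velocity_zeroes_all_but_galilei(self, props):
        nums = cc.dimensionless_numbers(
            props, cc.ReferenceScales(length_scale=10e-6), u_star=0.0, D=1e-12
        )
        assert nums.reynolds == nums.rayleigh == nums.peclet == 0.0
        assert nums.galilei > 0

    @pytest.mark.parametrize("L_um,expected", [(20.0, 0.162), (10.0, 0.0203)])
    def test_galilei_values(self, props, L_um, expected):
        nums = cc.dimensionless_numbers(
            props, cc.ReferenceScales(length_scale=L_um * 1e-6), u_star=0.0, D=1e-12
        )
        assert nums.galilei == pytest.approx(expected, rel=2e-2)

    def test_zero_diffusivity_rejected(self, props):
        with pytest.raises(InvalidInputError):
            cc.dimensionless_numbers(
                props, cc.ReferenceScales(length_scale=1e-5), u_star=1e-8, D=0.0
            )

    @given(
        c=st.floats(min_value=0.1, max_value=10.0),
        L=st.floats(min_value=1e-6, max_value=1e-4),
        u=st.floats(min_value=1e-10, max_value=1e-5),
    )
    @settings(deadline=None)
    def test_scaling_under_length_rescaling(self, c, L, u):
        """Re, Ra, Pe scale linearly with L; Ga cubically."""
        props = cc.FluidProperties()
        n1 = cc.dimensionless_numbers(props, cc.ReferenceScales(L), u, 1e-12)
        n2 = cc.dimensionless_numbers(props, cc.ReferenceScales(c * L), u, 1e-12)
        assert n2.reynolds == pytest.approx(c * n1.reynolds, rel=1e-9)
        assert n2.rayleigh == pytest.approx(c * n1.rayleigh, rel=1e-9)
        assert n2.peclet == pytest.approx(c * n1.peclet, rel=1e-9)
        assert n2.galilei == pytest.approx(c**3 * n1.galilei, rel=1e-9)

    @given(
        u_star=st.floats(min_value=0.0, max_value=0.39e-6),
        L=st.floats(min_value=1e-6, max_value=20e-6),
    )
    @settings(deadline=None)
    def test_stokes_regime_for_simulated_range(self, u_star, L):
        """Re, Ga, Ra < 1 over the whole simulated (u*, L) envelope."""
        props = cc.FluidProperties()
        nums = cc.dimensionless_numbers(props, cc.ReferenceScales(L), u_star, 1e-12)
        assert nums.reynolds < 1
        assert nums.galilei < 1
        assert nums.rayleigh < 1


class TestConfig:
    def test_yaml_overrides_with_defaults(self, tmp_path):
        cfg = tmp_path / "props.yaml"
        cfg.write_text("fluid_properties:\n  kinematic_viscosity: 1.0e-6\n")
        p = cc.FluidProperties.from_yaml(cfg)
        assert p.kinematic_viscosity == 1.0e-6
        assert p.reference_density == 993.38  # untouched default

    def test_temperature_conversions_roundtrip(self):
        assert cc.celsius_to_kelvin(37.0) == pytest.approx(310.15)
        assert cc.kelvin_to_celsius(cc.celsius_to_kelvin(42.5)) == pytest.approx(42.5)
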