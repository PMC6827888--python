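"""Buoyant-flow solver: quiescent/conduction limits, independent Stokes
oracles, circulation structure, linearity and convergence."""

import math

import numpy as np
import pytest
from scipy.integrate import solve_bvp

import cytoconvect as cc
from cytoconvect.errors import ConvergenceError, InvalidInputError
from cytoconvect.flow import conduction_profile_concentric

T_BODY = 310.15


class TestQuiescentLimit:
    def test_zero_delta_T_gives_zero_flow(self, flow2d_quiescent):
        assert flow2d_quiescent.max_speed_um_s < 1e-10
        assert np.allclose(flow2d_quiescent.T, T_BODY, atol=1e-9)
        assert all(v < 1e-10 for v in flow2d_quiescent.residuals.values())

    def test_residual_norms_zero_at_rest(self, flow2d_quiescent):
        res = cc.residual_norms(flow2d_quiescent)
        assert all(v < 1e-12 for v in res.values())


class TestConductionOracle:
    @pytest.mark.parametrize(
        "r,expected",
        [(4.3, 311.15), (10.0, 310.15), (7.15, 310.4507)],
    )
    def test_3d_profile_values(self, r, expected):
        T = conduction_profile_concentric(r, 4.3, 10.0, 311.15, 310.15, dimension=3)
        assert T == pytest.approx(expected, abs=1e-4)

    def test_2d_profile_boundary_values(self):
        assert conduction_profile_concentric(4.3, 4.3, 10, 311.15, 310.15, 2) == pytest.approx(311.15)
        assert conduction_profile_concentric(10, 4.3, 10, 311.15, 310.15, 2) == pytest.approx(310.15)

    def test_radius_outside_interval_rejected(self):
        with pytest.raises(InvalidInputError):
            conduction_profile_concentric(3.0, 4.3, 10.0, 311.15, 310.15)

    def test_gravity_off_recovers_conduction_2d(self, mesh2d_concentric):
        """g = 0, concentric walls: u = 0 and T is the log conduction profile."""
        sol = cc.solve_flow(
            mesh2d_concentric,
            cc.FluidProperties(gravity=0.0),
            cc.ThermalBC(T_BODY, T_BODY + 1.0),
        )
        assert sol.max_speed_um_s < 1e-12
        r = np.clip(np.linalg.norm(mesh2d_concentric.points, axis=1), 4.3, 10.0)
        exact = conduction_profile_concentric(r, 4.3, 10.0, T_BODY + 1, T_BODY, 2)
        err = np.linalg.norm(sol.T - exact) / np.linalg.norm(exact - T_BODY)
        assert err < 0.01

    def test_gravity_off_recovers_conduction_3d(self, props):
        geom = cc.spherical_cell_geometry(dimension=3, offset=0.0)
        mesh = cc.build_spherical_cell(geom, subdivisions=2, n_radial=5)
        sol = cc.solve_flow(
            mesh, cc.FluidProperties(gravity=0.0), cc.ThermalBC(T_BODY, T_BODY + 1)
        )
        assert sol.max_speed_um_s < 1e-12
        r = np.clip(np.linalg.norm(mesh.points, axis=1), 4.3, 10.0)
        exact = conduction_profile_concentric(r, 4.3, 10.0, T_BODY + 1, T_BODY, 3)
        err = np.linalg.norm(sol.T - exact) / np.linalg.norm(exact - T_BODY)
        assert err < 0.01


def _concentric_annulus_oracle_2d(a, b, dT, props):
    """Independent closed-form route: mode-1 stream function F(r) cos(phi)
    of the buoyant Stokes problem, mu L^2 F = rho0 g beta theta'(r), as a
    two-point BVP.  Returns (max upwelling, max downwelling) in m/s."""
    mu = props.dynamic_viscosity
    C = props.reference_density * props.gravity * props.thermal_expansion

    def thp(r):
        return dT / (r * np.log(a / b))

    def rhs(r, y):
        F, Fp, G, Gp = y
        return np.vstack(
            [Fp, G - Fp / r + F / r**2, Gp, (C / mu) * thp(r) - Gp / r + G / r**2]
        )

    def bcs(ya, yb):
        return np.array([ya[0], ya[1], yb[0], yb[1]])

    r = np.linspace(a, b, 801)
    sol = solve_bvp(rhs, bcs, r, np.zeros((4, r.size)), tol=1e-8, max_nodes=100000)
    assert sol.status == 0
    rr = np.linspace(a, b, 4000)
    F, Fp = sol.sol(rr)[0], sol.sol(rr)[1]
    u_y = np.concatenate([-Fp, -F / rr])  # phi = 0 and phi = pi/2 extremes
    return float(u_y.max()), float(-u_y.min())


class TestStokesOracle:
    def test_concentric_2d_matches_stream_function_bvp(self, mesh2d_concentric, props):
        """FEM vs independent biharmonic stream-function oracle, ΔT = 1 °C."""
        up_o, down_o = _concentric_annulus_oracle_2d(4.3e-6, 10e-6, 1.0, props)
        sol = cc.solve_flow(mesh2d_concentric, props, cc.ThermalBC(T_BODY, T_BODY + 1))
        w = sol.vertical_velocity_um_s()
        assert w.max() == pytest.approx(up_o * 1e6, rel=0.03)
        assert -w.min() == pytest.approx(down_o * 1e6, rel=0.03)


class TestCirculationStructure:
    def test_upwelling_exceeds_downwelling_when_heated(self, flow2d_heated):
        w = flow2d_heated.vertical_velocity_um_s()
        assert w.max() > -w.min() > 0

    def test_fountain_pattern_up_over_nucleus(self, flow2d_heated, geom2d):
        """Warm fluid rises above the heated nucleus, sinks near the membrane."""
        pts = flow2d_heated.mesh.points
        w = flow2d_heated.vertical_velocity_um_s()
        above = (np.abs(pts[:, 0] - 2.0) < 2.0) & (pts[:, 1] > 4.5) & (pts[:, 1] < 8.5)
        near_wall = np.linalg.norm(pts, axis=1) > 9.0
        assert w[above].mean() > 0
        assert w[near_wall & (pts[:, 1] > 0)].max() < w[above].max()

    def test_eccentric_major_minor_circulation(self, flow2d_heated):
        """Offset nucleus: stronger circulation on the wide (left) side."""
        pts = flow2d_heated.mesh.points
        speed = flow2d_heated.speed_um_s()
        left = pts[:, 0] < 2.0 - 4.3
        right = pts[:, 0] > 2.0 + 4.3
        assert speed[left].max() > speed[right].max()

    def test_temperature_maximum_principle(self, flow2d_heated):
        assert flow2d_heated.T.min() >= T_BODY - 1e-6
        assert flow2d_heated.T.max() <= T_BODY + 1.0 + 1e-6

    def test_closed_circulation_zero_net_flux(self, flow2d_heated):
        net, gross = cc.net_plane_flux(flow2d_heated)
        assert abs(net) < 0.01 * gross


class TestLinearityAndModes:
    def test_max_velocity_linear_in_delta_T(self, mesh2d, props):
        """Stokes regime: max |u| proportional to ΔT within 5 % over 0.1-13."""
        ups = {}
        for dT in (0.1, 1.0, 13.0):
            sol = cc.solve_flow(mesh2d, props, cc.ThermalBC(T_BODY, T_BODY + dT))
            ups[dT] = cc.max_vertical_velocities(sol)[0]
        for dT in (0.1, 13.0):
            assert ups[dT] / dT == pytest.approx(ups[1.0], rel=0.05)

    def test_boussinesq_agrees_with_full_density(self, mesh2d, props):
        """beta*theta <= 0.005: the two density treatments agree within 1 %."""
        bc = cc.ThermalBC(T_BODY, T_BODY + 13.0)
        full = cc.solve_flow(mesh2d, props, bc, cc.SolverOptions(boussinesq=False))
        bous = cc.solve_flow(mesh2d, props, bc, cc.SolverOptions(boussinesq=True))
        assert bous.max_speed_um_s == pytest.approx(full.max_speed_um_s, rel=0.01)

    def test_grid_convergence_under_refinement(self, mesh2d, flow2d_heated, props):
        fine = mesh2d.refined()
        sol_f = cc.solve_flow(fine, props, cc.ThermalBC(T_BODY, T_BODY + 1))
        assert flow2d_heated.max_speed_um_s == pytest.approx(
            sol_f.max_speed_um_s, rel=0.05
        )


class TestResiduals:
    def test_converged_residuals_below_tolerance(self, flow2d_heated):
        res = cc.residual_norms(flow2d_heated)
        assert all(v <= 1e-6 for v in res.values())

    def test_perturbing_velocity_increases_momentum_residual(self, flow2d_heated):
        import copy

        base = cc.residual_norms(flow2d_heated)["momentum"]
        perturbed = copy.copy(flow2d_heated)
        u = flow2d_heated.u.copy()
        interior = np.setdiff1d(
            np.arange(len(u)), flow2d_heated.mesh.boundary_nodes()
        )
        u[interior[0], 0] += 10 * np.abs(u).max()
        perturbed.u = u
        assert cc.residual_norms(perturbed)["momentum"] > base

    def test_iteration_budget_exhaustion_raises_with_history(self, mesh2d, props):
        with pytest.raises(ConvergenceError) as exc:
            cc.solve_flow(
                mesh2d, props, cc.ThermalBC(T_BODY, T_BODY + 1),
                cc.SolverOptions(tolerance=1e-30, max_outer_iterations=2),
            )
        assert len(exc.value.residual_history) == 2

    def test_bad_wall_temperature_rejected(self):
        with pytest.raises(InvalidInputError):
            cc.ThermalBC(membrane_temperature=float("nan"), nucleus_temperature=310.15)
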