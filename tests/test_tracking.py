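"""Particle tracking: determinism, confinement, Brownian statistics,
streamline fidelity and regime classification."""

import math

import numpy as np
import pytest
from scipy.integrate import solve_ivp

import cytoconvect as cc
from cytoconvect.errors import InvalidInputError
from cytoconvect.flow import FlowSolution, SolverOptions, ThermalBC
from cytoconvect.tracking import FlowInterpolator

T_BODY = 310.15


def _synthetic_rotation(mesh, center, omega):
    """FlowSolution whose velocity is rigid rotation about ``center`` (rad/s);
    streamlines are exact circles inside the annulus."""
    rel = mesh.points - np.asarray(center)
    u_um = omega * np.column_stack([-rel[:, 1], rel[:, 0]])
    return FlowSolution(
        mesh=mesh, u=u_um * 1e-6, p=np.zeros(mesh.n_nodes),
        T=np.full(mesh.n_nodes, T_BODY), iterations=1, residuals={},
        residual_history=[], props=cc.FluidProperties(),
        bc=ThermalBC(T_BODY, T_BODY), options=SolverOptions(),
    )


class TestDeterminismAndConfinement:
    def test_same_seed_bit_identical(self, flow2d_heated):
        spec = cc.ParticleSpec(diffusivity=0.05, start=(-2.0, -2.0))
        a = cc.track_particle(flow2d_heated, spec, dt=0.01, n_steps=500, seed=7)
        b = cc.track_particle(flow2d_heated, spec, dt=0.01, n_steps=500, seed=7)
        assert np.array_equal(a.positions, b.positions)
        assert not np.array_equal(
            a.positions,
            cc.track_particle(flow2d_heated, spec, dt=0.01, n_steps=500, seed=8).positions,
        )

    def test_ensemble_member_equals_single_run(self, flow2d_heated):
        spec = cc.ParticleSpec(diffusivity=0.05, start=(-2.0, -2.0))
        ens = cc.track_ensemble(flow2d_heated, spec, 0.01, 200, seeds=[3, 4])
        single = cc.track_particle(flow2d_heated, spec, 0.01, 200, seed=4)
        assert np.array_equal(ens[1].positions, single.positions)

    def test_every_point_inside_fluid(self, flow2d_heated, geom2d):
        spec = cc.ParticleSpec(diffusivity=0.5, start=(-2.0, -2.0))
        for tr in cc.track_ensemble(flow2d_heated, spec, 0.02, 500, seeds=range(5)):
            assert np.all(geom2d.membrane_signed_distance(tr.positions) <= 1e-9)
            assert np.all(geom2d.nucleus.signed_distance(tr.positions) >= -1e-9)

    def test_stationary_when_no_flow_no_diffusion(self, flow2d_quiescent):
        spec = cc.ParticleSpec(diffusivity=0.0, start=(-2.0, -2.0))
        tr = cc.track_particle(flow2d_quiescent, spec, 0.1, 50, seed=0)
        assert np.allclose(tr.positions, tr.positions[0])

    def test_start_outside_fluid_rejected(self, flow2d_heated):
        with pytest.raises(InvalidInputError):
            cc.track_particle(
                flow2d_heated, cc.ParticleSpec(start=(2.0, 0.0)), 0.01, 10, seed=0
            )  # inside the nucleus

    def test_oversized_step_rejected(self, flow2d_heated):
        with pytest.raises(InvalidInputError):
            cc.track_particle(
                flow2d_heated,
                cc.ParticleSpec(diffusivity=100.0, start=(-2.0, -2.0)),
                dt=100.0, n_steps=1, seed=0,
            )


class TestStreamlineFidelity:
    def test_deterministic_tracer_follows_streamline(self, mesh2d):
        """D = 0 on a rotational field: the path stays within one element
        diameter of the high-order streamline-integration oracle over a
        full circuit."""
        omega = 0.02
        flow = _synthetic_rotation(mesh2d, (2.0, 0.0), omega)
        spec = cc.ParticleSpec(diffusivity=0.0, start=(2.0, 6.0))
        dt = 0.05
        n = int(round(2 * math.pi / omega / dt))
        tr = cc.track_particle(flow, spec, dt, n, seed=0)
        interp = FlowInterpolator(mesh2d, flow.velocity_um_s)
        oracle = solve_ivp(
            lambda t, x: interp.velocity(x[None, :])[0],
            (0.0, n * dt), [2.0, 6.0], rtol=1e-9, atol=1e-12, dense_output=True,
        )
        dev = np.linalg.norm(tr.positions - oracle.sol(tr.timestamps).T, axis=1)
        assert dev.max() < mesh2d.element_sizes().max()


class TestBrownianStatistics:
    def test_msd_matches_2dDt_in_3d(self, flow3d_quiescent_coarse):
        """Free Brownian motion far from walls: MSD = 2·3·D·t."""
        spec = cc.ParticleSpec(diffusivity=0.01, start=(-5.0, 0.0, 0.0))
        trs = cc.track_ensemble(flow3d_quiescent_coarse, spec, 0.1, 50, seeds=range(400))
        msd = cc.ensemble_msd(trs)
        t_end = msd["t"].iloc[-1]
        assert msd["msd"].iloc[-1] == pytest.approx(6 * 0.01 * t_end, rel=0.10)

    def test_msd_weak_convergence_in_dt(self, flow3d_quiescent_coarse):
        spec = cc.ParticleSpec(diffusivity=0.01, start=(-5.0, 0.0, 0.0))
        final = []
        for dt, n in ((0.2, 25), (0.1, 50)):
            trs = cc.track_ensemble(flow3d_quiescent_coarse, spec, dt, n, seeds=range(400))
            final.append(cc.ensemble_msd(trs)["msd"].iloc[-1])
        assert final[0] == pytest.approx(final[1], rel=0.10)

    def test_advective_msd_bounded_by_circulation(self, mesh2d):
        """Pure advection on closed circular streamlines: MSD stays bounded
        by the squared circulation diameter (with a small allowance for the
        outward drift of the explicit-Euler integrator) instead of growing
        linearly like Brownian motion."""
        flow = _synthetic_rotation(mesh2d, (2.0, 0.0), 0.05)
        spec = cc.ParticleSpec(diffusivity=0.0, start=(2.0, 6.0))
        tr = cc.track_particle(flow, spec, 0.05, 4000, seed=0)
        msd = cc.ensemble_msd([tr])
        assert msd["msd"].max() <= 1.05 * (2 * 6.0) ** 2
        # bounded, not diffusive: the second circuit adds no spread
        half = len(msd) // 2
        assert msd["msd"].iloc[half:].max() <= 1.01 * msd["msd"].iloc[:half].max()

    def test_single_stationary_trajectory_msd_zero(self, flow2d_quiescent):
        tr = cc.track_particle(
            flow2d_quiescent, cc.ParticleSpec(diffusivity=0.0, start=(-2.0, -2.0)),
            0.1, 20, seed=0,
        )
        assert np.all(cc.ensemble_msd([tr])["msd"] == 0.0)

    def test_mismatched_timestamps_rejected(self, flow2d_quiescent):
        spec = cc.ParticleSpec(diffusivity=0.0, start=(-2.0, -2.0))
        a = cc.track_particle(flow2d_quiescent, spec, 0.1, 10, seed=0)
        b = cc.track_particle(flow2d_quiescent, spec, 0.2, 10, seed=0)
        with pytest.raises(InvalidInputError):
            cc.ensemble_msd([a, b])


class TestSettling:
    def test_stokes_settling_speed_value(self, props):
        """(rho_p - rho_f) g d² / (18 mu) ≈ 4.5e-4 μm/s for the 0.1 μm tracer."""
        spec = cc.ParticleSpec(density=1050.0, diameter=0.1)
        assert spec.settling_velocity_um_s(props) == pytest.approx(4.46e-4, rel=0.01)

    def test_settling_moves_particle_down(self, flow2d_quiescent):
        spec = cc.ParticleSpec(diffusivity=0.0, start=(-2.0, -2.0), settling=True)
        tr = cc.track_particle(flow2d_quiescent, spec, 1.0, 100, seed=0)
        assert tr.positions[-1, 1] < tr.positions[0, 1]


class TestRegimeClassification:
    def test_pure_advection_is_convection_dominated(self, flow2d_heated):
        spec = cc.ParticleSpec(diffusivity=0.0, start=(-2.0, -2.0))
        trs = cc.track_ensemble(flow2d_heated, spec, 0.01, 200, seeds=[0])
        assert cc.classify_regime(trs, flow2d_heated) == "convection-dominated"

    def test_pure_diffusion_is_diffusion_dominated(self, flow2d_quiescent):
        spec = cc.ParticleSpec(diffusivity=0.05, start=(-2.0, -2.0))
        trs = cc.track_ensemble(flow2d_quiescent, spec, 0.01, 200, seeds=range(20))
        assert cc.classify_regime(trs, flow2d_quiescent) == "diffusion-dominated"

    def test_physiological_gradient_does_not_dominate(self, flow2d_heated):
        """ΔT = 1 °C with D = 0.1 μm²/s: convection does not dominate."""
        spec = cc.ParticleSpec(diffusivity=0.1, start=(-2.0, -2.0))
        trs = cc.track_ensemble(flow2d_heated, spec, 0.01, 1000, seeds=range(30))
        assert cc.classify_regime(trs, flow2d_heated) != "convection-dominated"

    def test_drift_monotone_in_delta_T(self, mesh2d, props):
        """The along-flow drift distance grows with ΔT (regime ordering):
        measured with D = 0 so the advective signal is noise-free."""
        from cytoconvect.tracking import FlowInterpolator

        drifts = []
        for dT in (1.0, 13.0):
            sol = cc.solve_flow(mesh2d, props, cc.ThermalBC(T_BODY, T_BODY + dT))
            spec = cc.ParticleSpec(diffusivity=0.0, start=(-2.0, -2.0))
            (tr,) = cc.track_ensemble(sol, spec, 0.01, 500, seeds=[0])
            interp = FlowInterpolator(sol.mesh, sol.velocity_um_s)
            u = interp.velocity(tr.positions[:-1])
            norm = np.linalg.norm(u, axis=1, keepdims=True)
            uhat = np.where(norm > 0, u / np.where(norm > 0, norm, 1), 0.0)
            drifts.append(
                float(np.sum(np.einsum("nd,nd->n", np.diff(tr.positions, axis=0), uhat)))
            )
        assert drifts[1] > drifts[0] > 0

    def test_empty_ensemble_rejected(self, flow2d_heated):
        with pytest.raises(InvalidInputError):
            cc.classify_regime([], flow2d_heated)
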