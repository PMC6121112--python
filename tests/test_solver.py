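"""Monodomain solver tests: spectral diffusion, reaction, Strang stepping."""

import numpy as np
import pytest
from scipy import fft as sfft
from scipy.linalg import expm

from rotoremu.fk import FKParams, reaction_substep
from rotoremu.protocol import StimulusEvent, measure_cable_cv
from rotoremu.solver import (GridSpec, ProbeRecorder, TissueState, cable_grid,
                             diffusion_step, reaction_step, run_simulation,
                             smoke_grid, strang_step)


def dense_spectral_propagator(n, L, D_ms, dt):
    """Independent oracle: dense matrix exponential of the cosine-spectral
    Neumann Laplacian on a cell-centered 1D grid."""
    C = sfft.dct(np.eye(n), type=2, axis=0, norm="ortho")
    kap2 = (np.pi * np.arange(n) / L) ** 2
    A = C.T @ np.diag(-kap2) @ C
    return expm(D_ms * dt * A)


class TestDiffusion:
    def test_uniform_field_unchanged(self):
        g = GridSpec(Lx=2.0, Ly=2.0, nx=16, ny=16)
        u = np.full((16, 16), 0.37)
        out = diffusion_step(u, g.D_ms, 5.0, g)
        assert np.allclose(out, u, atol=1e-13)

    def test_single_cosine_mode_decays_analytically(self):
        g = GridSpec(Lx=3.0, Ly=1.0, nx=64, ny=1)
        u = np.cos(np.pi * g.x / g.Lx)[:, None]
        dt = 2.0
        out = diffusion_step(u, g.D_ms, dt, g)
        factor = np.exp(-g.D_ms * (np.pi / g.Lx) ** 2 * dt)
        assert np.allclose(out, factor * u, atol=1e-13)

    def test_matches_dense_matrix_exponential_oracle(self, rng):
        # 8x8 random field vs kron-composed dense propagator
        g = GridSpec(Lx=1.0, Ly=1.5, nx=8, ny=8)
        u = rng.random((8, 8))
        dt = 0.7
        Px = dense_spectral_propagator(8, g.Lx, g.D_ms, dt)
        Py = dense_spectral_propagator(8, g.Ly, g.D_ms, dt)
        expected = (np.kron(Px, Py) @ u.ravel()).reshape(8, 8)
        out = diffusion_step(u, g.D_ms, dt, g)
        assert np.max(np.abs(out - expected)) / np.max(np.abs(expected)) \
            < 1e-10

    def test_conserves_mean_and_contracts(self, rng):
        g = GridSpec(Lx=2.0, Ly=2.0, nx=32, ny=32)
        for _ in range(5):
            u = rng.standard_normal((32, 32))
            out = diffusion_step(u, g.D_ms, 3.0, g)
            assert out.mean() == pytest.approx(u.mean(), abs=1e-12)
            assert np.max(np.abs(out)) <= np.max(np.abs(u)) + 1e-12

    def test_shape_mismatch_rejected(self):
        g = GridSpec(Lx=1.0, Ly=1.0, nx=8, ny=8)
        with pytest.raises(ValueError):
            diffusion_step(np.zeros((4, 4)), g.D_ms, 1.0, g)


class TestReaction:
    def test_uniform_rest_tissue_unchanged(self, base_params):
        g = GridSpec(Lx=1.0, Ly=1.0, nx=8, ny=8)
        s = TissueState.rest(g)
        out = reaction_step(s, 0.1, base_params)
        assert np.allclose(out.u, 0.0, atol=1e-8)
        assert np.array_equal(out.v, s.v) and np.array_equal(out.w, s.w)

    def test_single_point_matches_cell_stepping(self, base_params):
        s = TissueState(u=np.full((1, 1), 0.4), v=np.full((1, 1), 0.7),
                        w=np.full((1, 1), 0.9))
        out = reaction_step(s, 0.1, base_params)
        u, v, w = reaction_substep(0.4, 0.7, 0.9, 0.1, base_params)
        assert out.u[0, 0] == u and out.v[0, 0] == v and out.w[0, 0] == w

    def test_local_error_is_second_order(self, base_params):
        # Richardson: e(dt)/e(dt/2) ~ 4 for one composite reaction step
        g = GridSpec(Lx=2.0, Ly=1.0, nx=64, ny=1)
        u0 = 0.6 * np.exp(-((g.x - 1.0) / 0.3) ** 2)[:, None]
        s0 = TissueState(u=u0, v=np.full_like(u0, 0.8),
                         w=np.full_like(u0, 0.8))

        def advance(dt, n):
            s = s0.copy()
            for _ in range(n):
                s = reaction_step(s, dt, base_params)
            return s.u

        ref = advance(0.4 / 64, 64)
        e1 = np.max(np.abs(advance(0.4, 1) - ref))
        e2 = np.max(np.abs(advance(0.2, 2) - ref))
        assert 2.5 < e1 / e2 < 8.0

    def test_non_finite_field_reported_with_index(self, base_params):
        g = GridSpec(Lx=1.0, Ly=1.0, nx=4, ny=4)
        s = TissueState.rest(g)
        s.u[2, 3] = 1e200  # will overflow through the polynomial terms
        with pytest.raises(FloatingPointError, match=r"\(2, 3\)"):
            reaction_step(s, 0.1, base_params)


class TestStrang:
    def test_zero_diffusion_reduces_to_reaction(self, base_params, rng):
        g = GridSpec(Lx=1.0, Ly=1.0, nx=16, ny=16, D=0.0)
        s = TissueState(u=rng.random((16, 16)), v=rng.random((16, 16)),
                        w=rng.random((16, 16)))
        out = strang_step(s, base_params, g)
        ref = reaction_step(s, g.dt, base_params)
        assert np.allclose(out.u, ref.u, atol=1e-12)
        assert out.t == pytest.approx(s.t + g.dt)

    def test_linear_regime_matches_exact_pde_solution(self, base_params):
        # below u_v the reaction is linear decay du/dt = -g_so_rest*u and the
        # initial cosine is a diffusion eigenfunction, so the PDE solution is
        # exact exponential decay (splitting commutes on eigenfunctions)
        g = GridSpec(Lx=2.0, Ly=1.0, nx=64, ny=1, D=1.0, dt=0.1)
        amp = 0.01
        u0 = amp * np.cos(np.pi * g.x / g.Lx)[:, None]
        s = TissueState(u=u0.copy(), v=np.ones_like(u0), w=np.ones_like(u0))
        T = 10.0
        for _ in range(int(T / g.dt)):
            s = strang_step(s, base_params, g)
        lam = base_params.g_so_rest + g.D_ms * (np.pi / g.Lx) ** 2
        exact = amp * np.exp(-lam * T) * np.cos(np.pi * g.x / g.Lx)[:, None]
        assert np.max(np.abs(s.u - exact)) / amp < 1e-4

    def test_global_convergence_order_two(self, base_params):
        # global error slope vs dt on a smooth pulse, fixed spatial grid
        g0 = GridSpec(Lx=2.0, Ly=1.0, nx=64, ny=1, D=1.0)
        u0 = 0.6 * np.exp(-((g0.x - 1.0) / 0.25) ** 2)[:, None]

        def run(dt, T=4.0):
            g = GridSpec(Lx=g0.Lx, Ly=g0.Ly, nx=g0.nx, ny=g0.ny, D=g0.D,
                         dt=dt)
            s = TissueState(u=u0.copy(), v=np.ones_like(u0),
                            w=np.ones_like(u0))
            for _ in range(int(round(T / dt))):
                s = strang_step(s, base_params, g)
            return s.u

        ref = run(0.0125)
        dts = np.array([0.2, 0.1, 0.05])
        errs = np.array([np.max(np.abs(run(dt) - ref)) for dt in dts])
        slope = np.polyfit(np.log(dts), np.log(errs), 1)[0]
        assert 1.7 < slope < 2.3


class TestRunSimulation:
    def test_zero_duration_returns_initial_snapshot(self, base_params):
        g = smoke_grid()
        probes = ProbeRecorder({"c": (g.Lx / 2, g.Ly / 2)}, interval=1.0)
        rec = run_simulation(TissueState.rest(g), base_params, g, T=0.0,
                             observers=[probes])
        assert rec.t_end == 0.0
        assert len(rec.probe_times) == 1 and rec.probe_times[0] == 0.0
        assert rec.termination_reason == "completed"

    def test_planar_wave_traverses_then_early_termination(self, base_params):
        g = smoke_grid()
        s1 = StimulusEvent(t_on=0.0, duration=2.0, amplitude=1.0,
                           region=(0.0, 0.5, 0.0, g.Ly))
        probes = ProbeRecorder({"far": (0.9 * g.Lx, g.Ly / 2)}, interval=1.0)
        rec = run_simulation(TissueState.rest(g), base_params, g,
                             stimuli=[s1], T=2000.0, observers=[probes])
        # wave reaches the far probe, tissue repolarizes, run stops early
        assert rec.probes["far"].max() > 0.9
        assert rec.termination_reason == "died_out"
        assert rec.t_end < 2000.0

    def test_stepping_is_deterministic(self, base_params, rng):
        g = GridSpec(Lx=1.875, Ly=1.875, nx=32, ny=32)
        u0 = rng.random((32, 32)) * 0.3

        def once():
            s = TissueState(u=u0.copy(), v=np.ones_like(u0),
                            w=np.ones_like(u0))
            for _ in range(200):
                s = strang_step(s, base_params, g)
            return s.u

        assert np.array_equal(once(), once())


class TestCableRestitution:
    def test_cv_increases_with_g_fi(self, base_params):
        grid = cable_grid(L=5.0, nx=160)
        cvs = []
        for g_fi in (2.1, 3.0, 3.9):  # the +-30% bounds and base
            cvs.append(measure_cable_cv(base_params.replace(g_fi=g_fi), grid,
                                        T=300.0))
        assert all(c is not None for c in cvs)
        assert cvs[0] < cvs[1] < cvs[2]
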