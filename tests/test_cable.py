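"""Cable integrator: stencil, stability, oracle equivalences, determinism."""

import dataclasses

import numpy as np
import pytest

from hhcable import (
    BlowUpError,
    CableGrid,
    DriveSpec,
    MembraneParams,
    StabilityError,
    integrate,
    integrate_space_clamped,
    laplacian,
    resting_field,
    step,
)
from hhcable.spikes import count_spikes_spatial


class TestLaplacian:
    def test_constant_field_maps_to_zero(self):
        assert np.allclose(laplacian(np.full(20, 3.7), 0.05), 0.0, atol=1e-12)

    def test_quadratic_has_exact_interior_second_derivative(self):
        x = np.linspace(0, 1, 11)
        lap = laplacian(x**2, x[1] - x[0])
        assert np.allclose(lap[1:-1], 2.0, atol=1e-9)

    def test_delta_gives_stencil(self):
        V = np.zeros(7)
        V[3] = 1.0
        lap = laplacian(V, 1.0)
        assert np.allclose(lap[2:5], [1.0, -2.0, 1.0])
        assert np.allclose(lap[[0, 1, 5, 6]], 0.0)

    def test_requires_three_nodes(self):
        with pytest.raises(ValueError):
            laplacian(np.zeros(2), 1.0)


class TestStability:
    def test_ratio_above_half_raises(self, params):
        bad = CableGrid(L=4.5, nx=4501, dt=0.1, t_end=1.0)  # r ~ 43
        with pytest.raises(StabilityError):
            bad.validate(params)

    def test_default_grid_has_margin(self, params, grid):
        assert grid.stability_ratio(params) < 0.25

    def test_warning_between_quarter_and_half(self):
        p = MembraneParams(radius=2e-4)  # D ~ 2.9e-3, r ~ 0.29
        g = CableGrid(L=1.0, nx=101, dt=0.01, t_end=1.0)
        assert 0.25 < g.stability_ratio(p) < 0.5
        with pytest.warns(UserWarning):
            g.validate(p)


class TestStep:
    def test_rest_is_an_equilibrium_of_the_field(self, params, small_grid):
        st0 = resting_field(small_grid)
        st1 = step(st0, small_grid, params, DriveSpec(mu=0.0))
        # leak equilibration leaves a ~4e-5 mV/step residual at most
        assert np.max(np.abs(st1.V - st0.V)) < 1e-4
        for _ in range(200):
            st1 = step(st1, small_grid, params, DriveSpec(mu=0.0))
        assert np.max(np.abs(st1.V)) < 0.02

    def test_single_step_noise_variance_matches_construction(self, params):
        """One Euler-Maruyama step from rest injects variance sigma^2 dt/dx."""
        g = CableGrid(L=2.0, nx=201, dt=0.01, t_end=1.0)
        p = dataclasses.replace(params, gK_bar=0.0, gNa_bar=0.0, gL=0.0)
        sigma = 0.4
        drive = DriveSpec(
            mu=0.0, noise_kind="additive", sigma=sigma, noise_window=(0.0, 2.0)
        )
        rng = np.random.default_rng(7)
        incs = []
        for _ in range(100):
            st1 = step(resting_field(g), g, p, drive, rng=rng)
            incs.append(st1.V)
        incs = np.concatenate(incs)
        expected = sigma**2 * g.dt / g.dx
        assert np.var(incs) == pytest.approx(expected, rel=0.05)

    def test_noise_respects_its_window_exactly(self, params, small_grid):
        drive = DriveSpec(
            mu=0.0, noise_kind="additive", sigma=5.0, noise_window=(0.5, 1.0)
        )
        quiet = dataclasses.replace(drive, sigma=0.0, noise_kind="none")
        rng = np.random.default_rng(3)
        noisy = step(resting_field(small_grid), small_grid, params, drive, rng=rng)
        clean = step(resting_field(small_grid), small_grid, params, quiet)
        x = small_grid.x
        outside = (x < 0.5) | (x >= 1.0)
        assert np.array_equal(noisy.V[outside], clean.V[outside])
        assert np.any(noisy.V[~outside] != clean.V[~outside])


class TestIntegrate:
    def test_pure_diffusion_matches_iterated_stencil_oracle(self, params):
        """With all conductances zero a delta relaxes as the discrete heat kernel."""
        g = CableGrid(L=0.5, nx=51, dt=0.01, t_end=1.0)
        p = dataclasses.replace(params, gK_bar=0.0, gNa_bar=0.0, gL=0.0)
        init = resting_field(g)
        init.V[25] = 1.0

        # brute-force oracle: repeated application of the mirrored stencil
        r = p.diffusion * g.dt / g.dx**2
        V = init.V.copy()
        for _ in range(g.nsteps):
            lap = np.empty_like(V)
            lap[1:-1] = V[2:] - 2 * V[1:-1] + V[:-2]
            lap[0] = 2 * (V[1] - V[0])
            lap[-1] = 2 * (V[-2] - V[-1])
            V = V + r * lap

        rec = integrate(init, g, p, DriveSpec(mu=0.0))
        assert np.max(np.abs(rec.final.V - V)) < 1e-10

    def test_uniform_field_equals_space_clamped_ode(self, params):
        """Zero-gradient cable == point model, node for node, any nx."""
        for nx in (3, 17):
            g = CableGrid(L=0.5, nx=nx, dt=0.01, t_end=30.0)
            drive = DriveSpec(mu=6.5, signal_window=(0.0, 0.5 + 1e-6))
            rec = integrate(resting_field(g), g, params, drive, snapshot_times=[30.0])
            ode = integrate_space_clamped(params, 6.5, 30.0, 0.01)
            # compare the full field at the end and one interior node over time
            assert np.max(np.abs(rec.final.V - ode["V"][-1])) < 1e-6

    def test_uniform_field_trajectory_matches_ode(self, params):
        g = CableGrid(L=0.2, nx=5, dt=0.01, t_end=30.0)
        drive = DriveSpec(mu=6.5, signal_window=(0.0, 0.2 + 1e-6))
        rec = integrate(
            resting_field(g), g, params, drive, probe_positions=[0.1]
        )
        ode = integrate_space_clamped(params, 6.5, 30.0, 0.01)
        assert np.max(np.abs(rec.probes[:, 0] - ode["V"][:-1])) < 1e-6

    def test_step_and_kernel_paths_agree(self, params, small_grid):
        """The compiled chunk kernel reproduces the numpy reference path."""
        g = CableGrid(L=1.5, nx=151, dt=0.01, t_end=2.0)
        drive = DriveSpec(
            mu=6.7, signal_window=(0.0, 0.1),
            noise_kind="additive", sigma=0.2, noise_window=(0.0, 1.0),
        )
        rec = integrate(
            resting_field(g), g, params, drive, rng=np.random.default_rng(11)
        )
        st = resting_field(g)
        rng = np.random.default_rng(11)
        for _ in range(g.nsteps):
            st = step(st, g, params, drive, rng=rng)
        assert np.max(np.abs(rec.final.V - st.V)) < 1e-8
        assert np.max(np.abs(np.asarray(rec.final.gating.m) - st.gating.m)) < 1e-10

    def test_identical_seeds_are_bit_identical(self, params, small_grid):
        drive = DriveSpec(
            mu=6.7, signal_window=(0.0, 0.1),
            noise_kind="additive", sigma=0.3, noise_window=(0.0, 1.5),
        )
        recs = [
            integrate(
                resting_field(small_grid), small_grid, params, drive,
                rng=np.random.default_rng(42),
            )
            for _ in range(2)
        ]
        assert np.array_equal(recs[0].final.V, recs[1].final.V)

    def test_subthreshold_drive_decays_to_rest(self, params, grid):
        drive = DriveSpec(mu=1.0, signal_window=(0.0, 0.1))
        rec = integrate(resting_field(grid), grid, params, drive)
        # no spike anywhere; the stimulated end holds a small depolarization
        assert np.max(rec.final.V) < 15.0
        assert np.max(np.abs(rec.final.V[grid.x > 1.0])) < 2.0

    def test_suprathreshold_drive_fills_cable_with_train(self, params, grid):
        drive = DriveSpec(mu=9.0, signal_window=(0.0, 0.1))
        rec = integrate(resting_field(grid), grid, params, drive)
        assert count_spikes_spatial(rec.final.V, grid.dx).n_spikes >= 5

    def test_blowup_names_node_and_time(self, params):
        g = CableGrid(L=0.5, nx=51, dt=0.01, t_end=5.0)
        drive = DriveSpec(mu=1e7, signal_window=(0.0, 0.2))
        with pytest.raises(BlowUpError, match=r"node \d+.*t="):
            integrate(resting_field(g), g, params, drive)

    def test_snapshots_are_recorded_at_requested_times(self, params, small_grid):
        drive = DriveSpec(mu=6.7, signal_window=(0.0, 0.1))
        times = [0.0, 10.0, 30.0]
        rec = integrate(
            resting_field(small_grid), small_grid, params, drive,
            snapshot_times=times,
        )
        assert [s.t for s in rec.snapshots] == pytest.approx(times)
        assert rec.snapshot_V().shape == (3, small_grid.nx)

    def test_wave_symmetry_for_interior_excitation(self, params):
        """Mid-cable stimulation emits the same number of spikes each way."""
        g = CableGrid(L=4.5, nx=451, dt=0.01, t_end=50.0)
        mid = g.L / 2
        drive = DriveSpec(mu=6.7, signal_window=(mid - 0.05, mid + 0.05))
        rec = integrate(resting_field(g), g, params, drive)
        sc = count_spikes_spatial(rec.final.V, g.dx)
        left = np.sum(sc.positions < mid)
        right = np.sum(sc.positions > mid)
        assert left == right
        assert left >= 1

    def test_grid_refinement_keeps_noise_free_count(self, params):
        """Halving dt and dx moves the deterministic count by at most 1."""
        coarse = CableGrid(L=4.5, nx=451, dt=0.01, t_end=100.0)
        fine = CableGrid(L=4.5, nx=901, dt=0.005, t_end=100.0)
        drive = DriveSpec(mu=6.7, signal_window=(0.0, 0.1))
        counts = [
            count_spikes_spatial(
                integrate(resting_field(g), g, params, drive).final.V, g.dx
            ).n_spikes
            for g in (coarse, fine)
        ]
        assert abs(counts[0] - counts[1]) <= 1

    def test_linear_cable_steady_state_matches_closed_form(self, params):
        """Passive cable under a window current reaches the analytic profile.

        With sodium and potassium blocked (and the leak reversal at rest)
        the model is the linear cable equation; the sealed-end steady
        state under a constant current on [0, a] is piecewise cosh.
        """
        p = dataclasses.replace(params, gK_bar=0.0, gNa_bar=0.0, V_L=0.0)
        g = CableGrid(L=1.0, nx=201, dt=0.01, t_end=100.0)
        a, mu = 0.2, 1.0
        drive = DriveSpec(mu=mu, signal_window=(0.0, a))
        rec = integrate(resting_field(g), g, p, drive)

        lam = np.sqrt(p.diffusion * p.C_m / p.gL)
        x = g.x
        # the driven node set [0, a) mirrors at the sealed end to the
        # continuum window [0, a - dx/2]; match the closed form to that
        a = a - g.dx / 2
        # V1 = mu/gL + A cosh(x/lam) on [0,a]; V2 = B cosh((L-x)/lam) on [a,L]
        ca, sa = np.cosh(a / lam), np.sinh(a / lam)
        cb, sb = np.cosh((g.L - a) / lam), np.sinh((g.L - a) / lam)
        # continuity of V and V' at x=a
        M = np.array([[ca, -cb], [sa, sb]])
        A, B = np.linalg.solve(M, [-mu / p.gL, 0.0])
        exact = np.where(
            x <= a, mu / p.gL + A * np.cosh(x / lam), B * np.cosh((g.L - x) / lam)
        )
        # half-open window: the node at x=a is undriven, match to V2 there
        exact[np.isclose(x, a)] = B * np.cosh((g.L - a) / lam)
        err = np.max(np.abs(rec.final.V - exact)) / np.max(np.abs(exact))
        assert err < 0.01
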