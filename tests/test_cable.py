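import math

import numpy as np
import pytest

from synplast.cable import (HodgkinHuxley, MembraneState, SpeciesField,
                            step_diffusion, step_voltage, total_amount)
from synplast.morphology import discretize, spiny_dendrite, unbranched_cable


def make_cable(length=100.0, radius=1.0, dl=1.0):
    return discretize(unbranched_cable(length, radius), dl)


class TestVoltage:
    def test_equilibrium_is_fixed_point(self):
        grid = make_cable()
        state = MembraneState(grid)
        v0 = state.v.copy()
        for _ in range(10):
            step_voltage(state, grid, None, 0.5)
        assert np.abs(state.v - v0).max() < 1e-8

    def test_sealed_end_steady_state_matches_cosh_profile(self):
        # constant current at one end of a passive sealed cable; the
        # steady-state profile is cosh((L-x)/lambda)/sinh-normalized
        grid = make_cable(length=100.0, dl=0.5)
        state = MembraneState(grid, g_leak=10.0, r_l=100.0)
        stim = np.zeros(grid.n)
        stim[0] = 0.05
        for _ in range(4000):
            step_voltage(state, grid, stim, 1.0)
        v = state.v - state.e_leak
        # lambda = sqrt(r_m / r_axial) per unit length
        g_per_um = state.g_leak_comp[0] / grid.length[0]
        r_ax = state.r_l * 1e-2 / (math.pi * 1.0**2)
        lam = math.sqrt(1.0 / (g_per_um * r_ax))
        x = (np.arange(grid.n) + 0.5) * grid.length[0]
        ref = np.cosh((100.0 - x) / lam)
        ref *= v[grid.n // 2] / ref[grid.n // 2]
        assert np.abs(v - ref).max() / v.max() < 0.01

    def test_grid_refinement_changes_profile_below_one_percent(self):
        profiles = {}
        for dl in (1.0, 0.5):
            grid = make_cable(length=50.0, dl=dl)
            state = MembraneState(grid, g_leak=10.0)
            stim = np.zeros(grid.n)
            stim[0] = 0.05
            for _ in range(3000):
                step_voltage(state, grid, stim, 1.0)
            x = (np.arange(grid.n) + 0.5) * grid.length[0]
            profiles[dl] = np.interp([10, 25, 40], x, state.v)
        dev = np.abs(profiles[1.0] - profiles[0.5])
        assert (dev / np.abs(profiles[0.5] - (-65.0))).max() < 0.01

    def test_hh_soma_sustained_spiking_dt_insensitive(self):
        counts = {}
        for dt in (0.025, 0.0125):
            grid = discretize(unbranched_cable(20.0, 10.0, "soma"), 20.0)
            state = MembraneState(grid, g_leak=0.0,
                                  hh=HodgkinHuxley(np.array([0])))
            stim = np.full(grid.n, 0.15)
            spikes, above = 0, False
            for _ in range(int(500.0 / dt)):
                step_voltage(state, grid, stim, dt)
                if state.v[0] > 0 and not above:
                    spikes += 1
                    above = True
                elif state.v[0] < -30:
                    above = False
            counts[dt] = spikes
        assert counts[0.025] > 10  # sustained periodic spiking
        assert abs(counts[0.025] - counts[0.0125]) <= 1

    def test_dt_validation(self):
        grid = make_cable()
        with pytest.raises(ValueError):
            step_voltage(MembraneState(grid), grid, None, 0.0)


class TestDiffusion:
    def test_zero_diffusivity_zero_source_unchanged(self):
        grid = make_cable()
        f = SpeciesField("x", grid, diffusivity=0.0)
        f.conc = np.linspace(0, 1, grid.n)
        c0 = f.conc.copy()
        step_diffusion(f, grid, 1.0)
        assert np.allclose(f.conc, c0, atol=1e-14)

    def test_negative_diffusivity_rejected(self):
        grid = make_cable()
        with pytest.raises(ValueError):
            SpeciesField("x", grid, diffusivity=-1.0)

    def test_point_deposit_spreads_as_gaussian(self):
        grid = make_cable(length=200.0)
        f = SpeciesField("x", grid, diffusivity=2.2e-10)
        mid = grid.n // 2
        f.conc[mid] = 1.0
        dt, t = 0.05, 0.0
        for _ in range(2000):
            step_diffusion(f, grid, dt)
            t += dt
        d_um = 2.2e-10 * 1e9
        x = np.arange(grid.n) - mid
        ref = np.exp(-x**2 / (4 * d_um * t))
        ref /= ref.sum()
        prof = f.conc / f.conc.sum()
        assert np.abs(prof - ref).max() / ref.max() < 0.02

    def test_amount_conserved_over_thousand_steps(self):
        grid = discretize(spiny_dendrite()[0], 1.0)  # branched tree
        f = SpeciesField("x", grid, diffusivity=2.2e-10)
        f.conc = np.abs(np.sin(np.arange(grid.n)))
        m0 = total_amount(f, grid)
        for _ in range(1000):
            step_diffusion(f, grid, 0.5)
        assert abs(total_amount(f, grid) - m0) / m0 < 1e-10

    def test_concentrations_stay_nonnegative(self):
        grid = make_cable(length=20.0)
        f = SpeciesField("x", grid, diffusivity=1e-9, tau=10.0)
        f.conc[0] = 1.0
        for _ in range(200):
            step_diffusion(f, grid, 1.0)
        assert (f.conc >= 0).all()

    def test_implicit_step_matches_fine_explicit_oracle(self):
        # 20-compartment cable: backward-Euler trajectory against an
        # explicit-Euler oracle at dt/1000 of the same flux operator
        grid = make_cable(length=20.0)
        d_um = 2.2e-10 * 1e9
        rng = np.random.default_rng(1)
        c0 = rng.random(grid.n)
        f = SpeciesField("x", grid, diffusivity=2.2e-10)
        f.conc = c0.copy()
        dt, nsteps = 1e-3, 50
        for _ in range(nsteps):
            step_diffusion(f, grid, dt)

        c = c0.copy()
        sub = dt / 1000.0
        coup = d_um * grid.a_face / grid.dist
        # chain topology: parent of i is i-1
        for _ in range(nsteps * 1000):
            j = coup[1:] * (c[:-1] - c[1:])
            flux = np.zeros_like(c)
            flux[1:] += j
            flux[:-1] -= j
            c += sub * flux / grid.volume
        err = np.linalg.norm(f.conc - c) / np.linalg.norm(c)
        assert err < 1e-4

    def test_stability_at_large_dt(self):
        grid = make_cable(length=50.0)
        f = SpeciesField("x", grid, diffusivity=1e-9)
        f.conc[0] = 100.0
        for _ in range(500):
            step_diffusion(f, grid, 1.0)
        assert np.isfinite(f.conc).all()
        assert f.conc.max() <= 100.0 + 1e-9


class TestTotalAmount:
    def test_uniform_and_zero(self):
        grid = make_cable(length=10.0)
        f = SpeciesField("x", grid)
        assert total_amount(f, grid) == 0.0
        f.conc[:] = 2.5
        assert total_amount(f, grid) == pytest.approx(
            2.5 * grid.volume.sum())

    def test_matches_independent_summation(self):
        grid = make_cable(length=17.0)
        f = SpeciesField("x", grid)
        rng = np.random.default_rng(3)
        f.conc = rng.random(grid.n)
        oracle = sum(float(f.conc[i]) * float(grid.volume[i])
                     for i in range(grid.n))
        assert total_amount(f, grid) == pytest.approx(oracle, rel=1e-14)

    def test_size_mismatch_rejected(self):
        g1 = make_cable(length=10.0)
        g2 = make_cable(length=20.0)
        f = SpeciesField("x", g1)
        with pytest.raises(ValueError):
            total_amount(f, g2)
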