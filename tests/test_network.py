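import math

import numpy as np
import pytest

from synplast.morphology import discretize, unbranched_cable
from synplast.network import (ConsolidationCell, MORPHO_PRESETS,
                              NetworkRecipe, RasterRecording,
                              SimulationPhase, StimulusProtocol,
                              build_network, compute_Q,
                              renormalized_threshold, run_phases,
                              sps_prp_coupling)
from synplast.plasticity.stc import PrpPool, StcParams, prp_step

SMALL = NetworkRecipe(n=60, n_exc=48, seed=5)


def tiny_raster(rates, t0=0.0, t1=1000.0):
    """Synthetic raster with the given per-population regular rates."""
    times, gids = [], []
    gid = 0
    for pop_rates in rates:
        for r in pop_rates:
            n = int(r * (t1 - t0) / 1000.0)
            times.extend(np.linspace(t0, t1, n, endpoint=False))
            gids.extend([gid] * n)
            gid += 1
    return RasterRecording(np.asarray(times), np.asarray(gids), [], {})


class TestBuildNetwork:
    def test_population_sizes(self):
        net = build_network(NetworkRecipe(n=2000, n_exc=1600, seed=1))
        assert net.exc_gids.size == 1600
        assert net.inh_gids.size == 400

    def test_zero_probability_no_synapses(self):
        net = build_network(NetworkRecipe(n=100, n_exc=80, p_conn=0.0))
        assert net.n_syn == 0

    def test_no_self_connections(self):
        net = build_network(SMALL)
        assert not np.diag(net.conn).any()

    def test_ee_synapse_count_binomial(self):
        net = build_network(NetworkRecipe(n=2000, n_exc=1600, seed=3))
        mean = 0.1 * 1600 * 1599
        sigma = math.sqrt(1600 * 1599 * 0.1 * 0.9)
        assert abs(net.n_syn - mean) < 3 * sigma

    def test_deterministic_per_seed(self):
        a = build_network(SMALL)
        b = build_network(SMALL)
        assert np.array_equal(a.conn, b.conn)

    def test_invalid_probability_rejected(self):
        with pytest.raises(ValueError, match="probability"):
            build_network(NetworkRecipe(p_conn=1.5))


class TestComputeQ:
    def test_equal_rates_give_zero(self):
        raster = tiny_raster([[8.0] * 4, [5.0] * 4, [5.0] * 8])
        pops = {"as": np.arange(4), "ans": np.arange(4, 8),
                "ctrl": np.arange(8, 16)}
        assert compute_Q(raster, pops, (0.0, 1000.0)) == pytest.approx(0.0)

    def test_arithmetic(self):
        raster = tiny_raster([[8.0] * 4, [6.0] * 4, [2.0] * 8])
        pops = {"as": np.arange(4), "ans": np.arange(4, 8),
                "ctrl": np.arange(8, 16)}
        assert compute_Q(raster, pops, (0.0, 1000.0)) == pytest.approx(0.5)

    def test_silent_assembly_errors(self):
        raster = tiny_raster([[0.0] * 4, [6.0] * 4, [2.0] * 8])
        pops = {"as": np.arange(4), "ans": np.arange(4, 8),
                "ctrl": np.arange(8, 16)}
        with pytest.raises(ValueError, match="silent"):
            compute_Q(raster, pops, (0.0, 1000.0))

    def test_invariant_under_uniform_rate_rescaling(self):
        pops = {"as": np.arange(4), "ans": np.arange(4, 8),
                "ctrl": np.arange(8, 16)}
        q1 = compute_Q(tiny_raster([[8.0] * 4, [6.0] * 4, [2.0] * 8]),
                       pops, (0.0, 1000.0))
        q2 = compute_Q(tiny_raster([[16.0] * 4, [12.0] * 4, [4.0] * 8]),
                       pops, (0.0, 1000.0))
        assert q1 == pytest.approx(q2)


class TestRenormalizedThreshold:
    def test_single_compartment(self):
        grid = discretize(unbranched_cable(2.0, 3.0), 5.0)
        v = math.pi * 9.0 * 2.0
        assert renormalized_threshold(1.5, grid) == pytest.approx(1.5 / v)

    def test_full_cell_against_independent_volume_sum(self):
        grid = MORPHO_PRESETS[("small", "long")].build_grid()
        assert grid.n == 48
        oracle = sum(float(v) for v in grid.volume)
        assert renormalized_threshold(2.10037, grid) == pytest.approx(
            2.10037 / oracle, rel=1e-12)

    def test_doubling_radii_divides_by_four(self):
        g1 = discretize(unbranched_cable(10.0, 1.0), 1.0)
        g2 = discretize(unbranched_cable(10.0, 2.0), 1.0)
        assert renormalized_threshold(1.0, g2) == pytest.approx(
            renormalized_threshold(1.0, g1) / 4.0)

    def test_zero_volume_rejected(self):
        grid = discretize(unbranched_cable(2.0, 3.0), 5.0)
        grid.volume = grid.volume * 0.0
        with pytest.raises(ValueError):
            renormalized_threshold(1.0, grid)


class TestPhases:
    def test_overlapping_phases_rejected(self):
        net = build_network(SMALL)
        with pytest.raises(ValueError, match="overlap"):
            run_phases(net, [SimulationPhase("full", 0, 100, 0.5),
                             SimulationPhase("full", 50, 150, 0.5)])

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError):
            SimulationPhase("turbo", 0, 1, 0.5)

    def test_state_roundtrip_identity(self):
        net = build_network(SMALL)
        run_phases(net, [SimulationPhase("full", 0, 200, 0.5)])
        snap = net.state_dict()
        net.restore(snap)
        snap2 = net.state_dict()
        for k in snap:
            assert np.array_equal(snap[k], snap2[k]), k

    def test_phase_splitting_invariance(self):
        # full(0.6 s) equals full(0.3)+ff(0 s)+full(0.3) bit for bit
        stim = StimulusProtocol(n_assembly=10, t_learn=100.0,
                                learn_dur=150.0, t_recall=400.0,
                                recall_dur=100.0)
        net1 = build_network(SMALL)
        r1 = run_phases(net1, [SimulationPhase("full", 0, 600, 0.5)], stim)
        net2 = build_network(SMALL)
        r2 = run_phases(net2, [SimulationPhase("full", 0, 300, 0.5),
                               SimulationPhase("fast-forward", 300, 300, 1e3),
                               SimulationPhase("full", 300, 600, 0.5)], stim)
        assert np.array_equal(r1.times, r2.times)
        assert np.array_equal(r1.gids, r2.gids)
        assert np.array_equal(net1.h, net2.h)

    def test_fast_forward_relaxes_h_exponentially(self):
        net = build_network(SMALL)
        p = net.recipe.stc
        # offset below theta_tag AND small enough that no neuron's summed
        # deviation reaches the PRP-synthesis threshold
        max_in = np.bincount(net.syn_post, minlength=net.recipe.n_exc).max()
        off = min(0.8 * p.theta_tag, 0.8 * p.theta_pro / max_in)
        net.h[:] = p.h0 + off
        hours = 2.0
        run_phases(net, [SimulationPhase("fast-forward", 0, hours * 3.6e6,
                                         10e3)])
        expected = p.h0 + off * math.exp(-0.1 * hours * 3.6e6 / p.tau_h)
        assert np.allclose(net.h, expected, rtol=1e-9)
        assert np.all(net.p_pool == 0.0)
        assert np.all(net.z == 0.0)

    def test_fast_forward_consolidates_tagged_synapses(self):
        net = build_network(SMALL)
        p = net.recipe.stc
        # potentiate every synapse onto neuron 0 beyond both thresholds
        idx = net.in_syn_idx(0)
        net.h[idx] = p.h0 + 3.9
        run_phases(net, [SimulationPhase("fast-forward", 0, 8 * 3.6e6,
                                         10e3)])
        assert net.z[idx].mean() > 0.3
        untouched = np.setdiff1d(np.arange(net.n_syn), idx)
        assert np.all(net.z[untouched] == 0.0)


class TestSpsPrpCoupling:
    def test_single_compartment_reduces_to_scalar_pool(self):
        grid = discretize(unbranched_cable(2e-3, 1e-3), 1.0)
        assert grid.n == 1
        p = StcParams()
        cell = ConsolidationCell(grid, p)
        pool = PrpPool(p)
        dev = 2.0 * p.theta_pro
        for _ in range(50):
            sps_prp_coupling(cell, [(0, dev)], 60e3)
            prp_step(pool, dev, 60e3)
        # concentration times volume equals the scalar pool amount exactly
        assert cell.prp.conc[0] == pytest.approx(pool.p, rel=1e-12)

    def test_missing_synthesis_compartment_rejected(self):
        grid = discretize(unbranched_cable(20.0, 1.0), 1.0)
        with pytest.raises(ValueError, match="synthesis"):
            ConsolidationCell(grid)

    def test_bad_synapse_compartment_rejected(self):
        grid = MORPHO_PRESETS[("small", "short")].build_grid()
        cell = ConsolidationCell(grid)
        with pytest.raises(ValueError):
            cell.step([(1000, 1.0)], 10.0)

    def test_slow_prp_diffusion_never_reaches_tips(self):
        # D_p = 1e-19 m^2/s: over 8 h the dendrite tips stay below 1% of
        # p_max even under continuous synthesis -> no late-phase change
        grid = MORPHO_PRESETS[("small", "long")].build_grid()
        p = StcParams()
        cell = ConsolidationCell(grid, p, d_p=1e-19)
        tip = grid.segment_slices[3][1] - 1  # apical tip
        basal_tip = grid.segment_slices[4][1] - 1
        dev = 10.0 * p.theta_pro
        for _ in range(2880):  # 8 h at 10-s steps
            cell.step([(basal_tip, dev)], 10e3)
        assert cell.synthesis_on
        assert cell.prp.conc[tip] < 0.01 * p.p_max
        assert cell.prp.conc[basal_tip] < 0.01 * p.p_max

    def test_fast_prp_diffusion_floods_the_cell(self):
        grid = MORPHO_PRESETS[("small", "long")].build_grid()
        p = StcParams()
        cell = ConsolidationCell(grid, p, d_p=1e-11)
        basal_tip = grid.segment_slices[4][1] - 1
        dev = 10.0 * p.theta_pro
        for _ in range(2880):
            cell.step([(basal_tip, dev)], 10e3)
        assert cell.prp.conc.min() > 0.9 * p.p_max

    def test_prp_amount_decays_with_tau_p_without_synthesis(self):
        grid = MORPHO_PRESETS[("small", "short")].build_grid()
        p = StcParams()
        cell = ConsolidationCell(grid, p, d_p=1e-13)
        cell.prp.conc[:] = 1.0
        m0 = cell.prp_total()
        nsteps, dt = 36, 100e3  # one hour = tau_p
        for _ in range(nsteps):
            cell.step([], dt)
        # implicit decay: (1 + dt/tau)^-n instead of exp(-t/tau)
        expected = m0 * (1.0 + dt / p.tau_p) ** -nsteps
        assert cell.prp_total() == pytest.approx(expected, rel=1e-9)


class TestMorphologicalNetworkSmoke:
    def test_short_run_produces_spikes_and_state(self):
        recipe = NetworkRecipe(n=40, n_exc=32, seed=2,
                               cell=MORPHO_PRESETS[("small", "short")])
        net = build_network(recipe)
        stim = StimulusProtocol(n_assembly=8, t_learn=50.0, learn_dur=100.0,
                                t_recall=1e9)
        raster = run_phases(net, [SimulationPhase("full", 0, 300, 0.5)],
                            stim)
        assert raster.times.size > 0
        assert np.isfinite(net.vm).all()
        assert np.isfinite(net.sps).all() and np.isfinite(net.prp).all()
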