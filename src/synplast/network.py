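"""Recurrent spiking networks with tagging-and-capture plasticity.

A network of leaky integrate-and-fire neurons (excitatory majority,
inhibitory minority, Bernoulli connectivity) whose excitatory-to-excitatory
synapses follow the two-phase calcium/tagging-and-capture rule.  A learning
stimulus drives a neuron assembly to high rates, potentiating the
within-assembly weights; a later recall stimulus to half the assembly tests
pattern completion, quantified by

``Q = (nu_ans - nu_ctrl) / nu_as``

where the three populations are the stimulated assembly half ('as'), the
non-stimulated half ('ans') and the remaining excitatory neurons ('ctrl'),
with mean rates taken in a 0.5-s window at recall.

Excitatory cells are either approximate point neurons or simplified
morphological cells (two-cylinder soma with a PRP-synthesis compartment,
apical and basal branches); for the morphological variant, recurrent
excitation arrives at the basal tip, external input at the apical tip and
inhibition at the soma, and the slow consolidation signals (SPS, PRP)
diffuse along the compartment tree.

All randomness is drawn from per-step counter-based streams, so a run is a
pure function of (configuration, seed) and splitting a run into phases at
any boundary leaves the spike raster unchanged.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .rng import NoiseStream
from .cable import (SpeciesField, step_diffusion, total_amount,
                    _tree_laplacian, UF_PER_CM2_TO_NF_PER_UM2,
                    OHM_CM_TO_MOHM_UM)
from .morphology import (consolidation_cell, discretize_consolidation_cell,
                         CompartmentGrid)
from .plasticity.stc import StcParams

__all__ = [
    "MorphoCellSpec", "NetworkRecipe", "StimulusProtocol", "SimulationPhase",
    "RasterRecording", "build_network", "run_phases", "compute_Q",
    "renormalized_threshold", "recall_experiment", "ConsolidationCell",
    "sps_prp_coupling", "MORPHO_PRESETS",
]

HOUR_MS = 3.6e6


@dataclass(frozen=True)
class MorphoCellSpec:
    """Geometry of the simplified consolidation cell (um).

    ``c_morpho`` multiplies the recurrent excitatory synaptic strength to
    correct the impact of postsynaptic potentials for the morphology.
    Diffusivities in m^2/s.
    """

    r_comp: float = 6.0
    l_soma: float = 12.0
    l_apical: float = 12.5
    l_basal: float = 5.0
    dl_comp: float = 1.0
    l_prp: float = 1.0
    c_morpho: float = 1.035
    d_sps: float = 1e-11
    d_p: float = 1e-11

    def build_grid(self) -> CompartmentGrid:
        morph = consolidation_cell(self.r_comp, self.l_soma, self.l_apical,
                                   self.l_basal, self.l_prp)
        return discretize_consolidation_cell(morph, self.dl_comp)


# Table-style presets: (cell size, dendrite length) -> spec
MORPHO_PRESETS = {
    ("small", "short"): MorphoCellSpec(6.0, 12.0, 12.5, 5.0, c_morpho=1.035),
    ("small", "long"): MorphoCellSpec(6.0, 12.0, 25.0, 10.0, c_morpho=1.020),
    ("large", "short"): MorphoCellSpec(12.0, 24.0, 12.5, 5.0, c_morpho=1.030),
    ("large", "long"): MorphoCellSpec(12.0, 24.0, 25.0, 10.0, c_morpho=1.018),
}


@dataclass(frozen=True)
class NetworkRecipe:
    """Population sizes, connectivity, neuron and synapse constants.

    The LIF constants and the static synaptic weights are configuration
    (mV, ms); plastic E->E weights are the early/late-phase state in mV.
    ``weight_scale`` optionally rescales all synaptic kicks for reduced
    networks (default 1: kicks are used as-is).
    """

    n: int = 500
    n_exc: int = 400
    p_conn: float = 0.1
    seed: int = 1
    # LIF constants
    v_rest: float = -65.0
    v_reset: float = -70.0
    v_thresh: float = -55.0
    tau_m: float = 10.0
    t_ref: float = 2.0
    # background drive (mean depolarization toward threshold, white noise)
    bg_mean: float = 6.5
    bg_sigma: float = 0.85  # mV / sqrt(ms)
    # synaptic kicks (mV) and conduction delay (ms)
    w_ei: float = 1.05
    w_ie: float = -6.3
    w_ii: float = -6.3
    delay: float = 3.0
    weight_scale: float = 1.0
    # converts the plastic coupling strength h + h0 z (mV) into the
    # delta-synapse membrane deflection (charge-transfer efficacy of a
    # brief current-based synapse relative to an instantaneous jump)
    syn_gain: float = 0.2
    # plasticity (in-vivo calcium correction applied at build time)
    stc: StcParams = field(default_factory=lambda: StcParams().in_vivo())
    # neuron model
    cell: Optional[MorphoCellSpec] = None  # None = approximate point neuron
    # passive cable constants for the morphological variant
    c_m: float = 1.0     # uF/cm^2
    r_l: float = 100.0   # Ohm*cm


@dataclass(frozen=True)
class StimulusProtocol:
    """Learning/recall pulse schedule (ms; rates in Hz, kicks in mV).

    The recall group is the first ``ceil(n_assembly/2)`` assembly members.
    The measurement window is 0.5 s centered 100 ms after recall onset.
    """

    n_assembly: int = 60
    t_learn: float = 2000.0
    learn_dur: float = 1000.0
    learn_rate: float = 900.0
    learn_kick: float = 2.0
    t_recall: float = 13000.0
    recall_dur: float = 500.0
    recall_rate: float = 900.0
    recall_kick: float = 2.0
    window: float = 500.0
    learning_enabled: bool = True
    recall_enabled: bool = True

    @property
    def window_bounds(self) -> tuple[float, float]:
        center = self.t_recall + 100.0
        return center - self.window / 2, center + self.window / 2


@dataclass(frozen=True)
class SimulationPhase:
    """A stretch of simulated time in 'full' or 'fast-forward' mode.

    Fast-forward phases advance only the slow variables (early-phase
    relaxation, late phase, PRP) at a coarse dt; no spiking, no calcium.
    """

    mode: str
    t0: float
    t1: float
    dt: float

    def __post_init__(self) -> None:
        if self.mode not in ("full", "fast-forward"):
            raise ValueError(f"unknown phase mode {self.mode!r}")
        if self.t1 < self.t0:
            raise ValueError("phase ends before it starts")


@dataclass
class RasterRecording:
    """Spike (time, gid) pairs plus probe traces and phase boundaries."""

    times: np.ndarray
    gids: np.ndarray
    phase_bounds: list
    probes: dict

    def rate(self, gids: np.ndarray, t0: float, t1: float) -> float:
        """Mean per-neuron firing rate (Hz) of ``gids`` in [t0, t1)."""
        sel = (self.times >= t0) & (self.times < t1) & np.isin(self.gids, gids)
        return float(sel.sum()) / (len(gids) * (t1 - t0) / 1000.0)


class Network:
    """Built network state (see :func:`build_network`)."""

    def __init__(self, recipe: NetworkRecipe):
        r = recipe
        if not (0.0 <= r.p_conn <= 1.0):
            raise ValueError(f"invalid connection probability {r.p_conn}")
        if r.n_exc > r.n:
            raise ValueError("n_exc exceeds n")
        self.recipe = r
        ne, n = r.n_exc, r.n
        conn_stream = NoiseStream((r.seed % 2**32, 0, 0, 0))
        u = conn_stream.uniforms(n * n).reshape(n, n)
        conn = u < r.p_conn
        np.fill_diagonal(conn, False)
        self.conn = conn
        self.exc_gids = np.arange(ne)
        self.inh_gids = np.arange(ne, n)

        # plastic E->E synapses, flat arrays grouped by presynaptic gid
        pre, post = np.nonzero(conn[:ne, :ne])
        order = np.argsort(pre, kind="stable")
        self.syn_pre = pre[order]
        self.syn_post = post[order]
        self.n_syn = self.syn_pre.size
        counts = np.bincount(self.syn_pre, minlength=ne)
        self.pre_slices = np.concatenate([[0], np.cumsum(counts)])
        by_post = np.argsort(self.syn_post, kind="stable")
        self.syn_by_post = by_post
        counts_post = np.bincount(self.syn_post, minlength=ne)
        self.post_slices = np.concatenate([[0], np.cumsum(counts_post)])

        p = r.stc
        self.h = np.full(self.n_syn, p.h0)
        self.z = np.zeros(self.n_syn)
        self.c = np.zeros(self.n_syn)
        self.p_pool = np.zeros(ne)  # per-neuron PRP (point variant)

        # static connectivity target lists
        self.ei_targets = [np.nonzero(conn[g, ne:])[0] + ne
                           for g in range(ne)]
        self.inh_targets = [np.nonzero(conn[g, :])[0] for g in range(ne, n)]

        # membrane state
        self.t = 0.0
        self.step_index = 0
        self.v = np.full(n, r.v_rest)
        self.ref_until = np.full(n, -np.inf)

        self.cell_grid = None
        if r.cell is not None:
            self._init_morpho(r.cell)

    # -- morphological variant -------------------------------------------

    def _init_morpho(self, spec: MorphoCellSpec) -> None:
        r = self.recipe
        grid = spec.build_grid()
        self.cell_grid = grid
        self.soma_comp = grid.prp_compartment
        self.apical_comp = grid.segment_slices[3][1] - 1
        self.basal_comp = grid.segment_slices[4][1] - 1
        cap = r.c_m * UF_PER_CM2_TO_NF_PER_UM2 * grid.area_lateral
        self.cap = cap
        self.cap_total = cap.sum()
        g_leak = cap / r.tau_m
        rl = r.r_l * OHM_CM_TO_MOHM_UM
        ax = np.where(grid.parent >= 0, grid.a_face / (rl * grid.dist), 0.0)
        self._vm_lap = _tree_laplacian(grid, ax)
        self._g_leak = g_leak
        self._vm_lu = None
        self._vm_dt = None
        # membrane potential per compartment for each excitatory cell
        self.vm = np.full((grid.n, r.n_exc), r.v_rest)
        # consolidation fields (per compartment x cell)
        self.sps = np.zeros((grid.n, r.n_exc))
        self.prp = np.zeros((grid.n, r.n_exc))
        self._sps_lu = None
        self._prp_lu = None
        self.theta_pro_star = renormalized_threshold(r.stc.theta_pro, grid)

    def _vm_solver(self, dt: float):
        if self._vm_lu is None or self._vm_dt != dt:
            a = self._vm_lap + sp.diags(self.cap / dt + self._g_leak)
            self._vm_lu = spla.splu(a.tocsc())
            self._vm_dt = dt
        return self._vm_lu

    def _species_solver(self, which: str, d_m2s: float, tau: float | None,
                        dt: float):
        key = "_sps_lu" if which == "sps" else "_prp_lu"
        cached = getattr(self, key)
        if cached is not None and cached[1] == (d_m2s, tau, dt):
            return cached[0]
        grid = self.cell_grid
        d_um = d_m2s * 1e9
        coup = np.where(grid.parent >= 0, d_um * grid.a_face / grid.dist, 0.0)
        a = _tree_laplacian(grid, coup) + sp.diags(grid.volume / dt)
        if tau is not None:
            a = a + sp.diags(grid.volume / tau)
        lu = spla.splu(a.tocsc())
        setattr(self, key, (lu, (d_m2s, tau, dt)))
        return lu

    # -- bookkeeping -----------------------------------------------------

    def out_syn(self, gid: int) -> slice:
        """Slice of plastic synapses whose presynaptic neuron is ``gid``."""
        return slice(self.pre_slices[gid], self.pre_slices[gid + 1])

    def in_syn_idx(self, gid: int) -> np.ndarray:
        """Indices of plastic synapses onto postsynaptic neuron ``gid``."""
        return self.syn_by_post[self.post_slices[gid]:self.post_slices[gid + 1]]

    def ee_weight(self) -> np.ndarray:
        """Current total weight of every plastic synapse (mV)."""
        return self.h + self.recipe.stc.h0 * self.z

    def state_dict(self) -> dict:
        """Snapshot of the carried state (for save/restore round trips)."""
        out = {"t": self.t, "step": self.step_index, "v": self.v.copy(),
               "ref": self.ref_until.copy(), "h": self.h.copy(),
               "z": self.z.copy(), "c": self.c.copy(),
               "p": self.p_pool.copy()}
        if self.cell_grid is not None:
            out |= {"vm": self.vm.copy(), "sps": self.sps.copy(),
                    "prp": self.prp.copy()}
        return out

    def restore(self, state: dict) -> None:
        self.t = state["t"]
        self.step_index = state["step"]
        self.v = state["v"].copy()
        self.ref_until = state["ref"].copy()
        self.h = state["h"].copy()
        self.z = state["z"].copy()
        self.c = state["c"].copy()
        self.p_pool = state["p"].copy()
        if self.cell_grid is not None:
            self.vm = state["vm"].copy()
            self.sps = state["sps"].copy()
            self.prp = state["prp"].copy()


def build_network(recipe: NetworkRecipe) -> Network:
    """Construct the network deterministically from its recipe and seed.

    Connectivity is Bernoulli(p_conn) without self-connections; plastic
    synapses exist only within the excitatory population, all other
    connections are static.
    """
    return Network(recipe)


def renormalized_threshold(theta_pro: float, grid: CompartmentGrid) -> float:
    """Concentration-space PRP threshold: ``theta_pro / total volume``.

    Comparing the somatic SPS *concentration* (instead of the total amount)
    against a threshold requires dividing by the cell volume.
    """
    v = grid.total_volume()
    if v <= 0:
        raise ValueError("total volume must be positive")
    return theta_pro / v


def compute_Q(raster: RasterRecording, subpopulations: dict,
              window: tuple[float, float]) -> float:
    """Pattern-completion coefficient from subpopulation rates in a window.

    ``subpopulations`` maps 'as', 'ans', 'ctrl' to gid arrays.  Raises if
    the stimulated assembly half is silent in the window (Q undefined).
    """
    t0, t1 = window
    nu_as = raster.rate(subpopulations["as"], t0, t1)
    nu_ans = raster.rate(subpopulations["ans"], t0, t1)
    nu_ctrl = raster.rate(subpopulations["ctrl"], t0, t1)
    if nu_as == 0.0:
        raise ValueError("Q undefined: stimulated assembly half is silent")
    return (nu_ans - nu_ctrl) / nu_as


def _step_key(seed: int, mech: int, step: int) -> NoiseStream:
    return NoiseStream((seed % 2**32, 1, mech, step % 2**32))


def _poisson_counts(u: np.ndarray, lam: float) -> np.ndarray:
    p0 = math.exp(-lam)
    p1 = p0 * (1.0 + lam)
    return (u >= p0).astype(np.float64) + (u >= p1)


def run_phases(net: Network, phases: Sequence[SimulationPhase],
               stim: StimulusProtocol | None = None) -> RasterRecording:
    """Run a contiguous schedule of full / fast-forward phases.

    State (weights, calcium, PRPs, membrane) carries across phase
    boundaries exactly.  Returns the spike raster of the full phases with
    probe traces of mean plastic weight and PRP.
    """
    for a, b in zip(phases[:-1], phases[1:]):
        if b.t0 < a.t1 - 1e-9:
            raise ValueError("overlapping phases")
    rec_times: list = []
    rec_gids: list = []
    probes = {"t": [], "mean_h_assembly": [], "mean_p": []}
    bounds = []
    for ph in phases:
        bounds.append((ph.mode, ph.t0, ph.t1))
        if ph.mode == "full":
            _run_full(net, ph, stim, rec_times, rec_gids, probes)
        else:
            _run_fast_forward(net, ph)
    times = (np.concatenate(rec_times) if rec_times else np.empty(0))
    gids = (np.concatenate(rec_gids) if rec_gids else
            np.empty(0, dtype=np.int64))
    return RasterRecording(times=times, gids=gids, phase_bounds=bounds,
                           probes={k: np.asarray(v) for k, v in probes.items()})


def _run_full(net: Network, ph: SimulationPhase,
              stim: StimulusProtocol | None,
              rec_times: list, rec_gids: list, probes: dict) -> None:
    r = net.recipe
    p = r.stc
    dt = ph.dt
    n, ne = r.n, r.n_exc
    nsteps = int(round((ph.t1 - ph.t0) / dt))
    if nsteps == 0:
        return
    delay_steps = max(1, int(round(r.delay / dt)))
    ca_delay_steps = max(1, int(round(p.tc_delay / dt)))
    buf_len = max(delay_steps, ca_delay_steps) + 1
    # in-flight deliveries persist across contiguous full phases, so a run
    # split at any boundary reproduces the unsplit raster exactly
    if getattr(net, "_bufs_key", None) == (dt,):
        kick_buf, ca_buf, pend_bufs = net._bufs
    else:
        kick_buf = np.zeros((buf_len, n))
        ca_buf = [[] for _ in range(buf_len)]
        pend_bufs = (np.zeros((buf_len, ne)), np.zeros((buf_len, ne)))
        net._bufs = (kick_buf, ca_buf, pend_bufs)
        net._bufs_key = (dt,)

    decay_v = math.exp(-dt / r.tau_m)
    bg_sigma_eff = r.bg_sigma * math.sqrt(r.tau_m / 2.0
                                          * (1.0 - decay_v ** 2))
    decay_c = math.exp(-dt / p.tau_c)
    relax_h = math.exp(-0.1 * dt / p.tau_h)
    sq_dt = math.sqrt(dt)

    morpho = net.cell_grid is not None
    if morpho:
        spec = r.cell
        vm_lu = net._vm_solver(dt)
        grid = net.cell_grid
        tau_sps = 1000.0
        sps_lu = net._species_solver("sps", spec.d_sps, tau_sps, dt)
        prp_lu = net._species_solver("prp", spec.d_p, p.tau_p, dt)
        # a kick of w mV delivered at a tip deposits the charge that
        # equalizes to a w-mV whole-cell deflection
        gain_basal = net.cap_total / net.cap[net.basal_comp]
        gain_apical = net.cap_total / net.cap[net.apical_comp]
        gain_soma = net.cap_total / net.cap[net.soma_comp]
        pend_basal, pend_soma = pend_bufs
        prp_source_rate = (p.p_max * grid.total_volume()
                           / (p.tau_p * grid.volume[net.soma_comp]))
        wscale = r.weight_scale * r.syn_gain * spec.c_morpho
    else:
        wscale = r.weight_scale * r.syn_gain

    assembly = np.arange(stim.n_assembly) if stim is not None else None
    n_recall = 0 if stim is None else -(-stim.n_assembly // 2)

    record_stride = max(1, int(round(100.0 / dt)))
    for k in range(nsteps):
        t = ph.t0 + k * dt
        step = net.step_index
        row = step % buf_len

        kicks = kick_buf[row].copy()
        kick_buf[row] = 0.0
        due_ca = ca_buf[row]
        ca_buf[row] = []
        for gid in due_ca:
            net.c[net.out_syn(gid)] += p.c_pre

        # external stimulation (delivered within the step, no extra delay)
        if stim is not None:
            if (stim.learning_enabled
                    and stim.t_learn <= t < stim.t_learn + stim.learn_dur):
                u = _step_key(r.seed, 2, step).uniforms(stim.n_assembly)
                counts = _poisson_counts(u, stim.learn_rate * dt / 1000.0)
                kicks[assembly] += counts * stim.learn_kick
            if (stim.recall_enabled
                    and stim.t_recall <= t < stim.t_recall + stim.recall_dur):
                u = _step_key(r.seed, 3, step).uniforms(n_recall)
                counts = _poisson_counts(u, stim.recall_rate * dt / 1000.0)
                kicks[assembly[:n_recall]] += counts * stim.recall_kick

        # background noise (exact OU update of the membrane mean/variance)
        noise = _step_key(r.seed, 1, step).normals(n)
        active = net.ref_until <= t + dt

        if morpho:
            # inhibitory neurons stay point-like
            vi = (r.v_rest + r.bg_mean
                  + (net.v[ne:] - r.v_rest - r.bg_mean) * decay_v
                  + kicks[ne:] + bg_sigma_eff * noise[ne:])
            net.v[ne:] = np.where(active[ne:], vi, r.v_reset)
            # excitatory cells: implicit leak/axial step on the shared tree
            rhs = (net.cap[:, None] / dt * net.vm
                   + net._g_leak[:, None] * (r.v_rest + r.bg_mean))
            net.vm = vm_lu.solve(rhs)
            # background acts coherently on the whole cell (no axial
            # currents), synaptic kicks deposit charge at their site
            net.vm += bg_sigma_eff * noise[:ne][None, :]
            net.vm[net.basal_comp] += pend_basal[row] * gain_basal
            net.vm[net.soma_comp] += pend_soma[row] * gain_soma
            net.vm[net.apical_comp] += kicks[:ne] * gain_apical
            pend_basal[row] = 0.0
            pend_soma[row] = 0.0
            inactive_e = ~active[:ne]
            if inactive_e.any():
                net.vm[:, inactive_e] = r.v_reset
            net.v[:ne] = net.vm[net.soma_comp]
        else:
            v = (r.v_rest + r.bg_mean
                 + (net.v - r.v_rest - r.bg_mean) * decay_v
                 + kicks + bg_sigma_eff * noise)
            net.v = np.where(active, v, r.v_reset)

        spiking = np.nonzero(active & (net.v >= r.v_thresh))[0]
        if spiking.size:
            net.v[spiking] = r.v_reset
            net.ref_until[spiking] = t + dt + r.t_ref
            if morpho:
                espike = spiking[spiking < ne]
                if espike.size:
                    net.vm[:, espike] = r.v_reset
            rec_times.append(np.full(spiking.size, t + dt))
            rec_gids.append(spiking.copy())
            # schedule deliveries
            drow = (step + delay_steps) % buf_len
            carow = (step + ca_delay_steps) % buf_len
            w_now = net.ee_weight()
            for gid in spiking:
                if gid < ne:
                    sl = net.out_syn(gid)
                    targets = net.syn_post[sl]
                    wk = w_now[sl] * wscale
                    if morpho:
                        pend_basal[drow][targets] += wk
                    else:
                        kick_buf[drow][targets] += wk
                    ti = net.ei_targets[gid]
                    kick_buf[drow][ti] += r.w_ei * r.weight_scale
                    ca_buf[carow].append(gid)
                    # postsynaptic calcium at this neuron's incoming synapses
                    net.c[net.in_syn_idx(gid)] += p.c_post
                else:
                    ti = net.inh_targets[gid - ne]
                    te = ti[ti < ne]
                    tin = ti[ti >= ne]
                    if morpho:
                        pend_soma[drow][te] += r.w_ie * r.weight_scale
                    else:
                        kick_buf[drow][te] += r.w_ie * r.weight_scale
                    kick_buf[drow][tin] += r.w_ii * r.weight_scale

        # plasticity: exact sub-threshold relaxation + gated Euler-Maruyama
        net.h = p.h0 + (net.h - p.h0) * relax_h
        hd_mask = net.c >= p.theta_d
        if hd_mask.any():
            idx = np.nonzero(hd_mask)[0]
            hp = net.c[idx] >= p.theta_p
            hvals = net.h[idx]
            drift = (p.gamma_p * (p.h_max - hvals) * hp
                     - p.gamma_d * hvals) / p.tau_h
            amp = p.sigma_pl * np.sqrt((hp + 1.0) / p.tau_h)
            zdraw = _step_key(r.seed, 4, step).normals(idx.size)
            net.h[idx] = np.clip(hvals + drift * dt + amp * sq_dt * zdraw,
                                 0.0, p.h_max)
        net.c *= decay_c

        # neuron-level PRP and late phase
        dev = np.abs(net.h - p.h0)
        dev_sum = np.bincount(net.syn_post, weights=dev, minlength=ne)
        if morpho:
            _sps_prp_morpho(net, dev_sum, dt, tau_sps, sps_lu, prp_lu,
                            prp_source_rate)
            p_local = net.prp[net.basal_comp]
            p_at_syn = p_local[net.syn_post]
        else:
            target = np.where(dev_sum >= p.theta_pro, p.p_max, 0.0)
            fac = math.exp(-dt / p.tau_p)
            net.p_pool = target + (net.p_pool - target) * fac
            p_at_syn = net.p_pool[net.syn_post]
        tag_up = (net.h - p.h0) > p.theta_tag
        tag_dn = (p.h0 - net.h) > p.theta_tag
        tagged = tag_up | tag_dn
        if tagged.any():
            ti = np.nonzero(tagged)[0]
            dz = (p_at_syn[ti] * p.f_int
                  * (np.where(tag_up[ti], 1.0 - net.z[ti],
                              -(net.z[ti] + 0.5)))) / p.tau_z
            net.z[ti] = np.clip(net.z[ti] + dz * dt, -0.5, 1.0)

        if k % record_stride == 0:
            probes["t"].append(t)
            if assembly is not None and assembly.size:
                asyn = np.isin(net.syn_pre, assembly) & np.isin(
                    net.syn_post, assembly)
                probes["mean_h_assembly"].append(
                    float(net.h[asyn].mean()) if asyn.any() else p.h0)
            else:
                probes["mean_h_assembly"].append(p.h0)
            probes["mean_p"].append(float(net.p_pool.mean()
                                          if not morpho
                                          else net.prp.mean()))
        net.t = t + dt
        net.step_index += 1


def _sps_prp_morpho(net: Network, dev_sum: np.ndarray, dt: float,
                    tau_sps: float, sps_lu, prp_lu,
                    prp_source_rate: float) -> None:
    """Diffusive SPS/PRP update for every excitatory cell (shared grid)."""
    grid = net.cell_grid
    p = net.recipe.stc
    vol = grid.volume
    # SPS: injected at the basal tip at rate dev_sum/tau_sps so that the
    # total amount tracks sum|h-h0| in the instantaneous-mixing limit
    src = np.zeros_like(net.sps)
    src[net.basal_comp] = dev_sum / tau_sps / vol[net.basal_comp]
    rhs = vol[:, None] * (net.sps / dt + src)
    net.sps = sps_lu.solve(rhs)
    # PRP synthesized in the soma synthesis compartment while the somatic
    # SPS concentration exceeds the volume-renormalized threshold
    sps_conc_soma = net.sps[net.soma_comp]
    on = sps_conc_soma >= net.theta_pro_star
    src_p = np.zeros_like(net.prp)
    src_p[net.soma_comp] = np.where(on, prp_source_rate, 0.0)
    rhs = vol[:, None] * (net.prp / dt + src_p)
    net.prp = prp_lu.solve(rhs)


def _run_fast_forward(net: Network, ph: SimulationPhase) -> None:
    """Advance only h-relaxation, z and p (no spiking, no calcium)."""
    r = net.recipe
    p = r.stc
    dt = ph.dt
    nsteps = int(round((ph.t1 - ph.t0) / dt))
    if nsteps > 0:
        # spiking is frozen: in-flight deliveries do not survive a
        # non-empty fast-forward phase
        net._bufs_key = None
    morpho = net.cell_grid is not None
    if morpho:
        tau_sps = 1000.0
        sps_lu = net._species_solver("sps", r.cell.d_sps, tau_sps, dt)
        prp_lu = net._species_solver("prp", r.cell.d_p, p.tau_p, dt)
        prp_source_rate = (p.p_max * net.cell_grid.total_volume()
                           / (p.tau_p * net.cell_grid.volume[net.soma_comp]))
    relax_h = math.exp(-0.1 * dt / p.tau_h)
    fac_p = math.exp(-dt / p.tau_p)
    for _ in range(nsteps):
        net.h = p.h0 + (net.h - p.h0) * relax_h
        dev = np.abs(net.h - p.h0)
        dev_sum = np.bincount(net.syn_post, weights=dev,
                              minlength=r.n_exc)
        if morpho:
            _sps_prp_morpho(net, dev_sum, dt, tau_sps, sps_lu, prp_lu,
                            prp_source_rate)
            p_at_syn = net.prp[net.basal_comp][net.syn_post]
        else:
            target = np.where(dev_sum >= p.theta_pro, p.p_max, 0.0)
            net.p_pool = target + (net.p_pool - target) * fac_p
            p_at_syn = net.p_pool[net.syn_post]
        tag_up = (net.h - p.h0) > p.theta_tag
        tag_dn = (p.h0 - net.h) > p.theta_tag
        tagged = tag_up | tag_dn
        if tagged.any():
            ti = np.nonzero(tagged)[0]
            dz = (p_at_syn[ti] * p.f_int
                  * (np.where(tag_up[ti], 1.0 - net.z[ti],
                              -(net.z[ti] + 0.5)))) / p.tau_z
            net.z[ti] = np.clip(net.z[ti] + dz * dt, -0.5, 1.0)
        net.t += dt
    net.step_index += nsteps


class ConsolidationCell:
    """SPS/PRP diffusion on a single cell, for probing the coupling.

    Synapses (given as compartment indices) inject the 'signal triggering
    PRP synthesis' (SPS) at a rate that makes the total SPS amount track
    ``sum |h-h0|`` in the instantaneous-mixing limit; while the SPS
    concentration at the soma center exceeds the volume-renormalized
    threshold, PRP is produced in the designated synthesis compartment and
    diffuses out to the synapses.

    A one-compartment grid reduces exactly to the scalar PRP pool update
    (:func:`synplast.plasticity.stc.prp_step`): mixing is instantaneous,
    so the amount-threshold comparison and the exact exponential update
    apply verbatim.
    """

    def __init__(self, grid: CompartmentGrid, params: StcParams | None = None,
                 d_sps: float = 1e-11, d_p: float = 1e-11,
                 tau_sps: float = 1000.0):
        if grid.prp_compartment is None and grid.n > 1:
            raise ValueError("grid has no designated PRP synthesis "
                             "compartment")
        self.grid = grid
        self.params = params or StcParams()
        self.soma_comp = grid.prp_compartment if grid.n > 1 else 0
        self.sps = SpeciesField("sps", grid, diffusivity=d_sps, tau=tau_sps)
        self.prp = SpeciesField("prp", grid, diffusivity=d_p,
                                tau=self.params.tau_p)
        self.tau_sps = tau_sps
        self.theta_pro_star = renormalized_threshold(self.params.theta_pro,
                                                     grid)
        self.synthesis_on = False

    def step(self, synapse_devs: Sequence[tuple[int, float]],
             dt: float) -> None:
        """Advance SPS and PRP by ``dt`` (ms).

        ``synapse_devs`` is a list of (compartment index, |h-h0|) pairs.
        """
        p = self.params
        grid = self.grid
        if grid.n == 1:
            # instantaneous mixing: scalar Eq on the amounts
            dev_sum = sum(d for _, d in synapse_devs)
            vol = grid.volume[0]
            self.sps.conc[0] = dev_sum / vol
            target = p.p_max if dev_sum >= p.theta_pro else 0.0
            amount = self.prp.conc[0]  # concentration == amount / vol
            self.prp.conc[0] = target + (amount - target) * math.exp(
                -dt / p.tau_p)
            self.synthesis_on = bool(target)
            return
        self.sps.source[:] = 0.0
        for comp, dev in synapse_devs:
            if not (0 <= comp < grid.n):
                raise ValueError(f"synapse compartment {comp} not on grid")
            self.sps.source[comp] += dev / self.tau_sps / grid.volume[comp]
        step_diffusion(self.sps, grid, dt)
        self.synthesis_on = (self.sps.conc[self.soma_comp]
                             >= self.theta_pro_star)
        self.prp.source[:] = 0.0
        if self.synthesis_on:
            self.prp.source[self.soma_comp] = (
                p.p_max * grid.total_volume()
                / (p.tau_p * grid.volume[self.soma_comp]))
        step_diffusion(self.prp, grid, dt)

    def prp_at(self, comp: int) -> float:
        """Local PRP concentration a synapse at ``comp`` would read."""
        return float(self.prp.conc[comp])

    def prp_total(self) -> float:
        return total_amount(self.prp, self.grid)


def sps_prp_coupling(cell: ConsolidationCell,
                     synapse_devs: Sequence[tuple[int, float]],
                     dt: float) -> ConsolidationCell:
    """One coupled SPS/PRP step on a cell (see :class:`ConsolidationCell`)."""
    cell.step(synapse_devs, dt)
    return cell


def recall_experiment(
    seeds: Sequence[int],
    recipe: NetworkRecipe | None = None,
    stim: StimulusProtocol | None = None,
    consolidate_hours: float = 0.0,
    dt: float = 0.5,
) -> dict:
    """Learning + (optional fast-forwarded consolidation) + recall.

    Runs one network per seed, computes Q in the 0.5-s recall window and
    returns per-seed values with the subpopulation rates.  With
    ``consolidate_hours > 0`` the schedule inserts a fast-forward phase
    between learning and recall (the recall time shifts accordingly).
    """
    recipe = recipe or NetworkRecipe()
    stim = stim or StimulusProtocol()
    if stim.n_assembly > recipe.n_exc:
        raise ValueError("assembly larger than excitatory population")
    qs, rates = [], []
    for seed in seeds:
        r = replace(recipe, seed=seed)
        net = build_network(r)
        if consolidate_hours > 0:
            t_ff0 = stim.t_learn + stim.learn_dur + 1000.0
            t_ff1 = t_ff0 + consolidate_hours * HOUR_MS
            st = replace(stim, t_recall=t_ff1 + 2000.0)
            phases = [
                SimulationPhase("full", 0.0, t_ff0, dt),
                SimulationPhase("fast-forward", t_ff0, t_ff1, 10e3),
                SimulationPhase("full", t_ff1,
                                st.window_bounds[1] + 100.0, dt),
            ]
        else:
            st = stim
            phases = [SimulationPhase("full", 0.0,
                                      st.window_bounds[1] + 100.0, dt)]
        raster = run_phases(net, phases, st)
        n_recall = -(-st.n_assembly // 2)
        pops = {
            "as": np.arange(n_recall),
            "ans": np.arange(n_recall, st.n_assembly),
            "ctrl": np.arange(st.n_assembly, r.n_exc),
        }
        q = compute_Q(raster, pops, st.window_bounds)
        qs.append(q)
        rates.append({k: raster.rate(v, *st.window_bounds)
                      for k, v in pops.items()})
    return {"Q": np.asarray(qs), "rates": rates,
            "mean_Q": float(np.mean(qs)), "seeds": list(seeds)}
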