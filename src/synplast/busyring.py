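"""Spike-propagation benchmark network ("busyring").

The network is a collection of rings of ``k`` neurons each, tuned so that
a single externally injected spike propagates around each ring forever:
every ring connection has delay ``t_delay`` and a suprathreshold weight,
so each neuron fires at exactly ``1 / (k * t_delay)``.  In addition, every
cell sends ``s`` zero-weight connections to random endpoints across the
whole network; these stress the event delivery machinery while having no
effect on the targets.  Optionally the zero-weight synapses carry
pair-based STDP state, whose traces evolve with the traffic while the
delivered amplitude stays zero — the spike raster is then unchanged.

The default cell is an integrate-and-fire point neuron (which makes the
propagation exactly periodic); a morphological "simple-branchy" variant
(random dendritic tree, Hodgkin-Huxley soma) is available through
:func:`simple_branchy_cell` for single-cell use.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .events import EventQueue, SpikeEvent, LifNeuron, lif_step
from .morphology import random_tree, Morphology
from .rng import NoiseStream
from .plasticity.stdp import StdpParams, StdpSynapse

__all__ = ["BusyringParams", "busyring_build", "busyring_run",
           "simple_branchy_cell"]


@dataclass(frozen=True)
class BusyringParams:
    n_cells: int = 16
    k: int = 4
    s: int = 0
    t_delay: float = 5.0
    weight: float = 30.0  # mV kick, suprathreshold
    dt: float = 0.025
    t_end: float = 200.0
    stdp_on_random: bool = False
    stdp: StdpParams = field(default_factory=lambda: StdpParams(
        a_pre=0.01, a_post=-0.01, tau_pre=10.0, tau_post=10.0, w_max=10.0))
    seed: int = 1


class BusyringNetwork:
    def __init__(self, p: BusyringParams):
        if p.k < 2 or p.n_cells % p.k != 0:
            raise ValueError(
                f"invalid ring size k={p.k} for {p.n_cells} cells "
                f"(k must be >= 2 and divide n_cells)")
        self.params = p
        n = p.n_cells
        # ring successor of each neuron
        self.ring_next = np.array([
            (g // p.k) * p.k + (g % p.k + 1) % p.k for g in range(n)])
        # s zero-weight random endpoints per cell
        stream = NoiseStream((p.seed % 2**32, 0, 0, 0))
        self.random_targets = []
        for g in range(n):
            if p.s:
                u = stream.uniforms(p.s)
                self.random_targets.append((u * n).astype(int) % n)
            else:
                self.random_targets.append(np.empty(0, dtype=int))
        self.stdp_syns = ({g: StdpSynapse(p.stdp, w=0.0)
                           for g in range(n)} if p.stdp_on_random else None)


def busyring_build(n_cells: int, k: int, s: int, t_delay: float,
                   weight: float = 30.0, **kwargs) -> BusyringNetwork:
    """Construct the ring network (validates that ``k`` divides the size)."""
    return BusyringNetwork(BusyringParams(n_cells=n_cells, k=k, s=s,
                                          t_delay=t_delay, weight=weight,
                                          **kwargs))


def busyring_run(net: BusyringNetwork) -> dict:
    """Grid-based simulation; one neuron per ring is kicked once at t=0.

    Returns the spike raster, the total delivered-event count and (with
    STDP enabled) the final trace/weight state of the zero-weight
    synapses.
    """
    p = net.params
    n = p.n_cells
    neurons = [LifNeuron() for _ in range(n)]
    queue = EventQueue()
    delivered = 0
    # external kick to neuron 0 of each ring, delivered in the first step
    for ring0 in range(0, n, p.k):
        queue.push(SpikeEvent(source=-1, target=(ring0, 0), t_emit=0.0,
                              t_deliver=0.0, weight=p.weight))
    nsteps = int(round(p.t_end / p.dt))
    times, gids = [], []
    for kstep in range(nsteps):
        t = kstep * p.dt
        inputs = np.zeros(n)
        # half-step tolerance: grid-aligned delivery times are immune to
        # floating-point drift of k*dt
        for ev in queue.pop_due(t + 0.5 * p.dt):
            delivered += 1
            gid = ev.target[0]
            inputs[gid] += ev.weight
            if net.stdp_syns is not None and ev.weight == 0.0:
                # traffic on the zero-weight synapse drives its traces;
                # the delivered amplitude stays the connection weight (0)
                net.stdp_syns[gid].on_pre_spike(t)
        spiking = []
        for gid in range(n):
            if inputs[gid] == 0.0 and neurons[gid].v == neurons[gid].v_rest:
                continue  # fast path: nothing to integrate
            _, spiked = lif_step(neurons[gid], inputs[gid], p.dt, t)
            if spiked:
                spiking.append(gid)
        for gid in spiking:
            t_spike = t + p.dt
            times.append(t_spike)
            gids.append(gid)
            queue.push(SpikeEvent(gid, (int(net.ring_next[gid]), 0),
                                  t_spike, t_spike + p.t_delay, p.weight))
            for tgt in net.random_targets[gid]:
                queue.push(SpikeEvent(gid, (int(tgt), 0), t_spike,
                                      t_spike + p.t_delay, 0.0))
            if net.stdp_syns is not None:
                net.stdp_syns[gid].on_post_spike(t_spike)
    out = {
        "times": np.asarray(times),
        "gids": np.asarray(gids, dtype=int),
        "delivered_events": delivered,
        "rate_per_neuron": len(times) / n / (p.t_end / 1000.0),
    }
    if net.stdp_syns is not None:
        out["stdp_traces"] = {g: (s.a_pre, s.a_post, s.w)
                              for g, s in net.stdp_syns.items()}
    return out


def simple_branchy_cell(seed: int = 1, depth: int = 2) -> Morphology:
    """Random-tree dendrite ("simple-branchy") morphology for one cell.

    The soma carries Hodgkin-Huxley dynamics in simulations; the dendrites
    are passive.  The tree is drawn per-cell from a counter-based stream,
    so each cell's geometry is reproducible.
    """
    stream = NoiseStream((seed % 2**32, 0, 7, 0))
    return random_tree(depth, stream)
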