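"""Point neurons, spike sources, delayed event delivery, post-spike dispatch.

The within-step ordering is fixed and documented: (1) deliver due
presynaptic events, (2) integrate the membrane, (3) detect spikes,
(4) dispatch the postsynaptic spike to every attached plastic mechanism,
(5) apply plasticity updates.  Spike times are aligned to the step grid
(threshold crossings are registered at the end of the step in which they
occur).
"""

from __future__ import annotations

import heapq
import itertools
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .rng import NoiseStream

__all__ = [
    "SpikeEvent",
    "EventQueue",
    "LifNeuron",
    "lif_step",
    "poisson_spikes",
    "regular_spikes",
    "post_event_dispatch",
]


@dataclass(frozen=True)
class SpikeEvent:
    """A spike in flight from a source to a target synapse."""

    source: int
    target: tuple[int, int]  # (gid, synapse index)
    t_emit: float
    t_deliver: float
    weight: float = 0.0

    def __post_init__(self) -> None:
        if self.t_deliver < self.t_emit:
            raise ValueError("delivery time precedes emission time")


class EventQueue:
    """Time-ordered pending events; ties keep stable insertion order."""

    def __init__(self) -> None:
        self._heap: list[tuple[float, int, SpikeEvent]] = []
        self._seq = itertools.count()

    def push(self, event: SpikeEvent) -> None:
        heapq.heappush(self._heap, (event.t_deliver, next(self._seq), event))

    def pop_due(self, t: float) -> list[SpikeEvent]:
        """All events with delivery time <= t, in delivery order."""
        due = []
        while self._heap and self._heap[0][0] <= t:
            due.append(heapq.heappop(self._heap)[2])
        return due

    def __len__(self) -> int:
        return len(self._heap)


@dataclass
class LifNeuron:
    """Leaky integrate-and-fire neuron with absolute refractory period.

    Parameters are configuration (mV, ms); the defaults are a conventional
    cortical-neuron setting, not values taken from any measurement.
    """

    v_rest: float = -65.0
    v_reset: float = -70.0
    v_thresh: float = -55.0
    tau_m: float = 10.0
    t_ref: float = 2.0
    v: float = None  # type: ignore[assignment]
    refractory_until: float = -math.inf

    def __post_init__(self) -> None:
        if self.v is None:
            self.v = self.v_rest


def lif_step(neuron: LifNeuron, inp: float, dt: float,
             t: float = 0.0) -> tuple[LifNeuron, bool]:
    """Advance one step; ``inp`` is the summed synaptic/stimulus drive in mV
    (a voltage deflection delivered within this step).

    Returns the neuron and whether it spiked at the end of the step.  Input
    during the refractory period is discarded and no spike can occur.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    t_end = t + dt
    if t_end <= neuron.refractory_until:
        neuron.v = neuron.v_reset
        return neuron, False
    decay = math.exp(-dt / neuron.tau_m)
    neuron.v = neuron.v_rest + (neuron.v - neuron.v_rest) * decay + inp
    if neuron.v >= neuron.v_thresh:
        neuron.v = neuron.v_reset
        neuron.refractory_until = t_end + neuron.t_ref
        return neuron, True
    return neuron, False


def poisson_spikes(rate: float, t0: float, t1: float,
                   stream: NoiseStream) -> np.ndarray:
    """Homogeneous Poisson spike times on [t0, t1); rate in Hz, times in ms.

    Reproducible per stream: identical (key, counter) state yields the
    identical realization.
    """
    if rate < 0:
        raise ValueError("rate must be non-negative")
    if t1 <= t0:
        raise ValueError("t1 must exceed t0")
    if rate == 0:
        return np.empty(0)
    mean_ms = 1000.0 / rate
    times = []
    t = t0
    while True:
        # draw gaps in chunks to amortize generator calls
        u = stream.uniforms(64)
        gaps = -mean_ms * np.log1p(-u)
        for g in gaps:
            t += g
            if t >= t1:
                return np.asarray(times)
            times.append(t)


def regular_spikes(interval: float, t0: float, t1: float,
                   phase: float = 0.0) -> np.ndarray:
    """Regular spike train with exact interval spacing on [t0, t1)."""
    if interval <= 0:
        raise ValueError("interval must be positive")
    start = t0 + phase
    n = max(0, math.ceil((t1 - start) / interval))
    times = start + interval * np.arange(n)
    return times[(times >= t0) & (times < t1)]


def post_event_dispatch(mechanisms: Iterable, t_spike: float) -> int:
    """Fan the postsynaptic spike time out to every attached mechanism.

    Every plastic mechanism co-located on the spiking cell observes the
    spike within the same timestep, without explicit modeling of action
    potential backpropagation; multiple mechanisms on one target (for
    example a conductance synapse and a calcium tracker) each receive the
    event once.  Returns the number of deliveries.
    """
    count = 0
    for mech in mechanisms:
        mech.on_post_spike(t_spike)
        count += 1
    return count
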