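"""Two-phase plasticity: calcium-driven early phase, tagging-and-capture
late phase.

The total synaptic weight ``w = h + h0 * z`` has an early-phase component
``h`` (mV) driven by the same bistable calcium rule as :mod:`.calcium`
(drift toward ``h0`` plus calcium-gated potentiation/depression and
activity-dependent noise), and a late-phase component ``z`` that changes
only when the synapse is *tagged* (``|h - h0| > theta_tag``) and
plasticity-related products (PRPs) are available.  PRPs are synthesized by
the neuron while the summed early-phase change of its synapses exceeds
``theta_pro`` and decay otherwise.

Because the calcium transient is an exogenous linear filter of the spike
trains, integration is hybrid: fine Euler-Maruyama steps inside the
analytically determined supra-threshold calcium windows, exact
exponential relaxation of ``h`` plus a coarse "fast-forward" grid for the
slow ``z``/``p`` dynamics everywhere else.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from ..rng import NoiseStream
from ..events import poisson_spikes, regular_spikes
from .calcium import calcium_events, threshold_windows

__all__ = ["StcParams", "StcSynapse", "PrpPool", "stc_step", "prp_step",
           "stc_protocol", "PROTOCOLS"]

HOUR_MS = 3.6e6


@dataclass(frozen=True)
class StcParams:
    """Early/late-phase parameters; mV, ms, umol/l.

    ``h0 = 0.5 * gamma_p / (gamma_p + gamma_d) * 10 mV`` is the baseline
    coupling strength; the tagging and PRP-synthesis thresholds are fixed
    fractions of it.  ``c_pre``/``c_post`` are the slice-conditioned
    values; network simulations multiply both by ``in_vivo_factor``.
    """

    h0: float = 4.20075
    tc_delay: float = 18.8
    c_pre: float = 1.0
    c_post: float = 0.2758
    in_vivo_factor: float = 0.6
    tau_c: float = 48.8
    tau_h: float = 688.4e3
    tau_p: float = 60 * 60e3
    tau_z: float = 60 * 60e3
    gamma_p: float = 1645.6
    gamma_d: float = 313.1
    theta_p: float = 3.0
    theta_d: float = 1.2
    sigma_pl: float = 2.90436
    h_max: float = 10.0
    p_max: float = 10.0
    theta_pro: float = 2.10037
    theta_tag: float = 0.840149
    f_int: float = 0.1
    r_comp: float = 1e-3
    l_cell: float = 2e-3
    literal_printed_noise: bool = False

    def in_vivo(self) -> "StcParams":
        """Calcium amplitudes corrected for in-vivo conditions."""
        return replace(self, c_pre=self.c_pre * self.in_vivo_factor,
                       c_post=self.c_post * self.in_vivo_factor)

    def drift_h(self, h, hp, hd):
        return (0.1 * (self.h0 - h)
                + self.gamma_p * (self.h_max - h) * hp
                - self.gamma_d * h * hd) / self.tau_h

    def noise_amp(self, hp, hd):
        s = hp + hd
        if self.literal_printed_noise:
            return self.sigma_pl * s
        return self.sigma_pl * math.sqrt(s / self.tau_h)


@dataclass
class StcSynapse:
    """Early/late-phase state of one excitatory-to-excitatory synapse."""

    params: StcParams = field(default_factory=StcParams)
    h: float = None  # type: ignore[assignment]
    z: float = 0.0
    c: float = 0.0
    t: float = 0.0
    stream: NoiseStream | None = None
    _pending_ca: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.h is None:
            self.h = self.params.h0

    @property
    def weight(self) -> float:
        """Total weight ``w = h + h0 z`` in mV."""
        return self.h + self.params.h0 * self.z

    @property
    def tagged(self) -> bool:
        return abs(self.h - self.params.h0) > self.params.theta_tag

    @property
    def deviation(self) -> float:
        """|h - h0|, the synapse's contribution to PRP-synthesis drive."""
        return abs(self.h - self.params.h0)

    def on_pre_spike(self, t: float) -> None:
        self._pending_ca.append(t + self.params.tc_delay)

    def on_post_spike(self, t: float) -> None:
        self.c += self.params.c_post


@dataclass
class PrpPool:
    """Per-neuron plasticity-related product concentration (umol/l)."""

    params: StcParams = field(default_factory=StcParams)
    p: float = 0.0


def prp_step(pool: PrpPool, deviation_sum: float, dt: float) -> PrpPool:
    """Exact exponential update of ``tau_p dp/dt = -p + p_max H[sum - theta_pro]``.

    ``deviation_sum`` is ``sum_synapses |h - h0|`` over the neuron's
    synapses (a single synapse contributes just its own deviation).
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    par = pool.params
    target = par.p_max if deviation_sum >= par.theta_pro else 0.0
    pool.p = target + (pool.p - target) * math.exp(-dt / par.tau_p)
    return pool


def _z_step(z: float, h: float, p: float, dt: float, par: StcParams) -> float:
    dev = h - par.h0
    up = 1.0 if dev > par.theta_tag else 0.0
    down = 1.0 if -dev > par.theta_tag else 0.0
    dz = (p * par.f_int * ((1.0 - z) * up - (z + 0.5) * down)) / par.tau_z
    return min(max(z + dz * dt, -0.5), 1.0)


def stc_step(syn: StcSynapse, pool: PrpPool, dt: float,
             due_events=()) -> tuple[StcSynapse, float]:
    """One full-detail step of the early/late-phase synapse.

    Applies due pre/post events (presynaptic calcium influx is scheduled
    ``tc_delay`` later), advances calcium, takes one Euler-Maruyama step of
    ``h`` (clipped to [0, h_max]), updates ``z`` from the neuron's local
    PRP concentration, and returns the synapse together with its
    ``|h - h0|`` contribution for the neuron-level PRP threshold sum.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    par = syn.params
    for kind, te in due_events:
        if kind == "pre":
            syn.on_pre_spike(te)
        elif kind == "post":
            syn.on_post_spike(te)
        else:
            raise ValueError(f"unknown event kind {kind!r}")
    t_next = syn.t + dt
    mature = [te for te in syn._pending_ca if te < t_next]
    syn._pending_ca = [te for te in syn._pending_ca if te >= t_next]
    syn.c += par.c_pre * len(mature)
    hp = 1.0 if syn.c >= par.theta_p else 0.0
    hd = 1.0 if syn.c >= par.theta_d else 0.0
    dh = par.drift_h(syn.h, hp, hd) * dt
    if (hp or hd) and syn.stream is not None:
        dh += par.noise_amp(hp, hd) * math.sqrt(dt) * syn.stream.normal()
    syn.h = min(max(syn.h + dh, 0.0), par.h_max)
    syn.z = _z_step(syn.z, syn.h, pool.p, dt, par)
    syn.c *= math.exp(-dt / par.tau_c)
    syn.t = t_next
    return syn, syn.deviation


# ---------------------------------------------------------------------------
# Classical induction protocols at a single synapse

def _tetanus(rate_hz: float, t0: float, dur: float) -> np.ndarray:
    return regular_spikes(1000.0 / rate_hz, t0, t0 + dur)


def _protocol_pre_times(name: str) -> np.ndarray:
    if name == "STET":  # 3 x 1 s at 100 Hz, 10 min apart
        return np.concatenate([_tetanus(100.0, t0, 1000.0)
                               for t0 in (0.0, 600e3, 1200e3)])
    if name == "WTET":  # single 0.2 s at 100 Hz
        return _tetanus(100.0, 0.0, 200.0)
    if name == "SLFS":  # 900 bursts (3 spikes at 20 Hz) at 1 Hz
        base = 1000.0 * np.arange(900)
        return np.sort(np.concatenate([base, base + 50.0, base + 100.0]))
    if name == "WLFS":  # 900 single spikes at 1 Hz
        return 1000.0 * np.arange(900)
    raise ValueError(
        f"unknown protocol {name!r}; available: STET, WTET, SLFS, WLFS")


PROTOCOLS = ("STET", "WTET", "SLFS", "WLFS")


class _CalciumWalker:
    """Running calcium value along a sorted jump list."""

    def __init__(self, events: np.ndarray, tau_c: float):
        self.ev = events
        self.tau = tau_c
        self.idx = 0
        self.t = 0.0
        self.c = 0.0

    def advance(self, t: float) -> float:
        while self.idx < len(self.ev) and self.ev[self.idx, 0] <= t:
            te, amp = self.ev[self.idx]
            self.c = self.c * math.exp(-(te - self.t) / self.tau) + amp
            self.t = te
            self.idx += 1
        self.c *= math.exp(-(t - self.t) / self.tau)
        self.t = t
        return self.c


def _fast_forward(h: float, z: float, p: float, t0: float, t1: float,
                  par: StcParams, dt_ff: float = 10e3,
                  record=None) -> tuple[float, float, float]:
    """Slow-variable integration over [t0, t1]: h relaxes toward h0
    exponentially, p follows its exact threshold update, z its tag-gated
    Euler update on the coarse grid (no spiking, no calcium)."""
    t = t0
    lam = 0.1 / par.tau_h
    while t < t1 - 1e-9:
        step = min(dt_ff, t1 - t)
        dev = abs(h - par.h0)
        target = par.p_max if dev >= par.theta_pro else 0.0
        p_new = target + (p - target) * math.exp(-step / par.tau_p)
        z = _z_step(z, h, 0.5 * (p + p_new), step, par)
        p = p_new
        h = par.h0 + (h - par.h0) * math.exp(-lam * step)
        t += step
        if record is not None:
            record(t, h, z, p)
    return h, z, p


def run_stc_synapse(pre_times: np.ndarray, post_times: np.ndarray,
                    params: StcParams, stream: NoiseStream | None,
                    t_end: float, dt: float = 0.5,
                    record=None) -> dict:
    """Hybrid integration of a single synapse plus its neuron's PRP pool.

    Fine Euler-Maruyama steps run only inside supra-``theta_d`` calcium
    windows; outside them the drift and noise vanish identically, so the
    exact relaxations apply.  Returns the final state and crossing flags.
    """
    par = params
    events = calcium_events(pre_times, post_times, par.c_pre, par.c_post,
                            par.tc_delay)
    windows = threshold_windows(events, par.tau_c, par.theta_d, t_end, pad=dt)
    walker = _CalciumWalker(events, par.tau_c)
    h, z, p = par.h0, 0.0, 0.0
    t = 0.0
    tag_crossed = False
    pro_crossed = False
    sqdt = math.sqrt(dt)
    for a, b in windows:
        if a > t:
            h, z, p = _fast_forward(h, z, p, t, a, par, record=record)
            t = a
        nsteps = max(1, int(math.ceil((b - a) / dt)))
        zn = stream.normals(nsteps) if stream is not None else None
        c = walker.advance(a)
        for k in range(nsteps):
            hp = 1.0 if c >= par.theta_p else 0.0
            hd = 1.0 if c >= par.theta_d else 0.0
            dh = par.drift_h(h, hp, hd) * dt
            if zn is not None and (hp or hd):
                dh += par.noise_amp(hp, hd) * sqdt * zn[k]
            h = min(max(h + dh, 0.0), par.h_max)
            dev = abs(h - par.h0)
            target = par.p_max if dev >= par.theta_pro else 0.0
            p = target + (p - target) * math.exp(-dt / par.tau_p)
            z = _z_step(z, h, p, dt, par)
            tag_crossed = tag_crossed or dev > par.theta_tag
            pro_crossed = pro_crossed or dev >= par.theta_pro
            c = walker.advance(a + (k + 1) * dt)
        t = a + nsteps * dt
        if record is not None:
            record(t, h, z, p)
    if t < t_end:
        h, z, p = _fast_forward(h, z, p, t, t_end, par, record=record)
    return {"h": h, "z": z, "p": p, "w": h + par.h0 * z,
            "tag_crossed": tag_crossed, "pro_crossed": pro_crossed}


def stc_protocol(name: str, seed: int = 1, n_trials: int = 10,
                 params: StcParams | None = None,
                 t_measure: float = 8 * HOUR_MS,
                 post_rate_hz: float = 0.2, p_evoke: float = 0.5,
                 t_evoke: float = 10.0, dt: float = 0.5) -> dict:
    """Run a classical induction protocol and summarize the weight outcome.

    The postsynaptic neuron's spontaneous activity is a Poisson train at
    ``post_rate_hz``; in addition, pathway stimulation evokes a
    postsynaptic spike ``t_evoke`` ms after a presynaptic pulse with
    probability ``p_evoke`` (fiber-bundle co-activation — essential for
    low-frequency depression, where single presynaptic transients alone
    never reach the depression threshold).  Returns per-trial states at
    ``t_measure`` and at the end of stimulation, plus a recorded trace of
    the first trial.
    """
    par = params or StcParams()
    pre = _protocol_pre_times(name)
    t_proto_end = float(pre.max()) + 5000.0
    out = {k: [] for k in ("h", "z", "p", "w", "tag_crossed", "pro_crossed")}
    h_end_proto = []
    trace = {"t": [], "h": [], "z": [], "p": []}
    for trial in range(n_trials):
        post_stream = NoiseStream((seed % 2**32, trial, 0, 0))
        evoke_stream = NoiseStream((seed % 2**32, trial, 2, 0))
        post = poisson_spikes(post_rate_hz, 0.0, t_measure, post_stream)
        if p_evoke > 0:
            u = evoke_stream.uniforms(pre.size)
            post = np.sort(np.concatenate([post, pre[u < p_evoke] + t_evoke]))

        def rec(t, h, z, p, _first=(trial == 0)):
            if _first:
                trace["t"].append(t)
                trace["h"].append(h)
                trace["z"].append(z)
                trace["p"].append(p)

        # identical noise stream: the trajectory on [0, t_proto_end] is the
        # same in both runs, so this reads off the end-of-protocol state
        mid = run_stc_synapse(pre, post, par,
                              NoiseStream((seed % 2**32, trial, 1, 0)),
                              t_proto_end, dt)
        h_end_proto.append(mid["h"])
        res = run_stc_synapse(pre, post, par,
                              NoiseStream((seed % 2**32, trial, 1, 0)),
                              t_measure, dt, record=rec)
        for k in out:
            out[k].append(res[k])
    return {k: np.asarray(v) for k, v in out.items()} | {
        "h_end_protocol": np.asarray(h_end_proto),
        "t_protocol_end": t_proto_end,
        "trace": {k: np.asarray(v) for k, v in trace.items()},
        "protocol": name,
    }
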