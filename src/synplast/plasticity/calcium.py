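"""Bistable calcium-based synaptic plasticity.

The synaptic weight ``w`` (dimensionless) relaxes in a double-well
potential with basins at 0 and 1 separated by ``w_star``; transient
calcium ``c`` — a leaky integrator driven by pre- and postsynaptic spikes
— gates potentiation (``c > theta_p``), depression (``c > theta_d``) and
an activity-dependent noise term:

``tau_w dw/dt = -w(1-w)(w*-w) + gamma_p (1-w) H[c-theta_p]
- gamma_d w H[c-theta_d] + xi(t)``

Presynaptic calcium influx is delayed by ``tc_delay`` after each
presynaptic spike (NMDA-receptor kinetics); postsynaptic influx is
immediate.  The noise ``xi = sigma_pl sqrt(tau_w (Hp + Hd)) Gamma(t)`` is
active only while calcium is above a threshold (a flag switches to the
form without the square root for sensitivity checks).

Because calcium is an exogenous linear filter of the spike trains, the
integrator spends fine Euler-Maruyama steps only inside the analytically
computed supra-threshold windows; outside them only the deterministic
cubic drift acts and is advanced with coarser steps.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from ..rng import NoiseStream

__all__ = [
    "GbParams", "GbSynapse", "gb_step", "gb_run", "gb_dp_curve",
    "calcium_events", "threshold_windows", "calcium_at",
]


# ---------------------------------------------------------------------------
# Calcium transient utilities (shared with the tagging-and-capture rule)

def calcium_events(pre_times: Sequence[float], post_times: Sequence[float],
                   c_pre: float, c_post: float,
                   tc_delay: float) -> np.ndarray:
    """Sorted (time, amplitude) jump list for the calcium transient."""
    ev = [(t + tc_delay, c_pre) for t in pre_times]
    ev += [(t, c_post) for t in post_times]
    ev.sort()
    return np.asarray(ev).reshape(-1, 2)


def calcium_at(events: np.ndarray, tau_c: float, t: float,
               c0: float = 0.0, t0: float = 0.0) -> float:
    """Calcium at time ``t`` (jumps at times <= t included)."""
    c = c0 * math.exp(-(t - t0) / tau_c)
    for te, amp in events:
        if t0 <= te <= t:
            c += amp * math.exp(-(t - te) / tau_c)
    return c


def threshold_windows(events: np.ndarray, tau_c: float, theta: float,
                      t_end: float, pad: float = 0.0) -> list[tuple[float, float]]:
    """Merged intervals on [0, t_end] where the calcium transient >= theta.

    ``pad`` extends each interval symmetrically (useful to capture the
    step-grid neighborhood of a crossing).
    """
    windows: list[list[float]] = []
    c = 0.0
    t = 0.0
    for te, amp in events:
        if te > t_end:
            break
        c *= math.exp(-(te - t) / tau_c)
        t = te
        c += amp
        if c >= theta:
            t_cross = t + tau_c * math.log(c / theta)
            a, b = t - pad, min(t_cross + pad, t_end)
            if windows and a <= windows[-1][1]:
                windows[-1][1] = max(windows[-1][1], b)
            else:
                windows.append([a, b])
    return [(max(a, 0.0), b) for a, b in windows]


# ---------------------------------------------------------------------------
# The bistable rule

@dataclass(frozen=True)
class GbParams:
    """Dimensionless weight/calcium; times in ms."""

    w_star: float = 0.5
    tc_delay: float = 13.7
    c_pre: float = 1.0
    c_post: float = 2.0
    tau_c: float = 20.0
    tau_w: float = 150_000.0  # 150 s
    gamma_p: float = 321.808
    gamma_d: float = 200.0
    theta_p: float = 1.3
    theta_d: float = 1.0
    sigma_pl: float = 2.8248
    literal_printed_noise: bool = False

    def drift(self, w, hp, hd):
        return (-w * (1.0 - w) * (self.w_star - w)
                + self.gamma_p * (1.0 - w) * hp
                - self.gamma_d * w * hd) / self.tau_w

    def noise_amp(self, hp, hd):
        """Coefficient of dW in the weight update."""
        s = hp + hd
        if self.literal_printed_noise:
            return self.sigma_pl * s
        return self.sigma_pl * np.sqrt(s / self.tau_w)


@dataclass
class GbSynapse:
    """Scalar synapse state for step-by-step simulation."""

    params: GbParams = field(default_factory=GbParams)
    w: float = 1.0
    c: float = 0.0
    t: float = 0.0
    stream: NoiseStream | None = None
    _pending_ca: list = field(default_factory=list)  # scheduled influx times

    def on_pre_spike(self, t: float) -> None:
        self._pending_ca.append(t + self.params.tc_delay)

    def on_post_spike(self, t: float) -> None:
        self.c += self.params.c_post


def gb_step(syn: GbSynapse, dt: float, due_events: Sequence = ()) -> GbSynapse:
    """Advance the synapse by one step of size ``dt``.

    ``due_events`` are ("pre"|"post", time) pairs due within this step:
    presynaptic spikes schedule a delayed calcium influx, postsynaptic
    spikes add calcium immediately.  Scheduled influxes maturing in this
    step are applied, then the weight takes one Euler-Maruyama step with
    the start-of-step calcium.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    p = syn.params
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
    for _ in mature:
        syn.c += p.c_pre
    hp = 1.0 if syn.c >= p.theta_p else 0.0
    hd = 1.0 if syn.c >= p.theta_d else 0.0
    dw = p.drift(syn.w, hp, hd) * dt
    if (hp or hd) and syn.stream is not None:
        dw += float(p.noise_amp(hp, hd)) * math.sqrt(dt) * syn.stream.normal()
    syn.w += dw
    syn.c *= math.exp(-dt / p.tau_c)
    syn.t = t_next
    return syn


def _advance_cubic(w: np.ndarray, duration: float, params: GbParams,
                   dt_coarse: float = 20.0) -> np.ndarray:
    """Deterministic sub-threshold relaxation (cubic drift only)."""
    remaining = duration
    while remaining > 1e-12:
        h = min(dt_coarse, remaining)
        w = w + params.drift(w, 0.0, 0.0) * h
        remaining -= h
    return w


def gb_run(pre_times: np.ndarray, post_times: np.ndarray,
           w0: np.ndarray, params: GbParams, stream: NoiseStream | None,
           t_end: float, dt: float = 0.5) -> np.ndarray:
    """Integrate the rule over [0, t_end] for a vector of trials.

    All trials share the (deterministic) calcium transient; noise-off runs
    pass ``stream=None``.  Fine steps are spent only while calcium exceeds
    the depression threshold.
    """
    p = params
    events = calcium_events(pre_times, post_times, p.c_pre, p.c_post,
                            p.tc_delay)
    windows = threshold_windows(events, p.tau_c, p.theta_d, t_end, pad=dt)
    w = np.array(w0, dtype=float, copy=True)
    t = 0.0
    for a, b in windows:
        w = _advance_cubic(w, a - t, p)
        nsteps = max(1, int(math.ceil((b - a) / dt)))
        c = calcium_at(events, p.tau_c, a)
        idx = np.searchsorted(events[:, 0], a, side="right") if len(events) else 0
        decay = math.exp(-dt / p.tau_c)
        sqdt = math.sqrt(dt)
        z = (stream.normals(nsteps * w.size).reshape(nsteps, w.size)
             if stream is not None else None)
        tk = a
        for k in range(nsteps):
            hp = 1.0 if c >= p.theta_p else 0.0
            hd = 1.0 if c >= p.theta_d else 0.0
            w += p.drift(w, hp, hd) * dt
            if z is not None and (hp or hd):
                w += float(p.noise_amp(hp, hd)) * sqdt * z[k]
            # calcium: decay plus jumps inside (tk, tk+dt]
            c *= decay
            t_next = tk + dt
            while idx < len(events) and events[idx, 0] <= t_next:
                c += events[idx, 1] * math.exp(-(t_next - events[idx, 0])
                                               / p.tau_c)
                idx += 1
            tk = t_next
        t = tk
    w = _advance_cubic(w, t_end - t, p)
    return w


def gb_dp_curve(delta_ts: Sequence[float], n_pairs: int = 60,
                pair_rate: float = 1.0, n_trials: int = 400,
                seed: int = 1, params: GbParams | None = None,
                dt: float = 0.5, tail: float = 1000.0) -> dict:
    """Mean weight change versus pre/post lag for the pairing protocol.

    Each synapse receives ``n_pairs`` spike pairs at ``pair_rate`` Hz with
    lag ``delta_t`` (post minus pre, ms); the initial weight is drawn
    uniformly from {0, 1}.  The observable is the trial mean of
    ``w_end - w_start``; a normal-approximation 95% confidence band is
    returned alongside.
    """
    if len(delta_ts) == 0:
        raise ValueError("empty delta_t grid")
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    params = params or GbParams()
    period = 1000.0 / pair_rate
    means, bands = [], []
    for j, d in enumerate(delta_ts):
        pre = period * np.arange(n_pairs)
        post = pre + d
        shift = -min(0.0, float(post.min()))
        pre, post = pre + shift, post + shift
        t_end = max(pre.max(), post.max()) + params.tc_delay + tail
        w0_stream = NoiseStream((seed % 2**32, j, 0, 0))
        w0 = (w0_stream.uniforms(n_trials) < 0.5).astype(float)
        noise = NoiseStream((seed % 2**32, j, 1, 0))
        w_end = gb_run(pre, post, w0, params, noise, t_end, dt)
        change = w_end - w0
        means.append(float(change.mean()))
        bands.append(1.96 * float(change.std(ddof=1)) / math.sqrt(n_trials))
    return {"delta_t": np.asarray(delta_ts, dtype=float),
            "mean_change": np.asarray(means),
            "ci95": np.asarray(bands)}
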