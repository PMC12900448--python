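"""Spike-driven homeostatic plasticity.

The plastic synapse weight jumps by ``dw_plus`` on every presynaptic spike
and by ``dw_minus`` (negative) on every postsynaptic spike, clipped to
``[0, w_max]``.  With ``dw_plus = |dw_minus|`` the weight is stationary
only when the postsynaptic rate equals the presynaptic rate, so the rule
regulates the neuron's output rate to the fixed rate of its plastic input.

:func:`run_homeostasis_experiment` reproduces the canonical paradigm: an
integrate-and-fire neuron driven by a fixed-rate plastic input and a
varying-rate static input (current-based delta synapses), with a silent
segment in the varying schedule during which the clipped weight limits the
compensation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from ..rng import NoiseStream

__all__ = ["HomeoParams", "HomeoSynapse", "homeo_on_spike",
           "run_homeostasis_experiment", "DEFAULT_SCHEDULE"]


@dataclass(frozen=True)
class HomeoParams:
    """Weights in nA."""

    dw_plus: float = 0.35
    dw_minus: float = -0.35
    w_init: float = 0.0
    w_max: float = 5.0


@dataclass
class HomeoSynapse:
    params: HomeoParams = field(default_factory=HomeoParams)
    w: float = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.w is None:
            self.w = self.params.w_init

    def on_pre_spike(self) -> None:
        self.w = min(max(self.w + self.params.dw_plus, 0.0),
                     self.params.w_max)

    def on_post_spike(self) -> None:
        self.w = min(max(self.w + self.params.dw_minus, 0.0),
                     self.params.w_max)


def homeo_on_spike(syn: HomeoSynapse, kind: str) -> HomeoSynapse:
    if kind == "pre":
        syn.on_pre_spike()
    elif kind == "post":
        syn.on_post_spike()
    else:
        raise ValueError(f"kind must be 'pre' or 'post', got {kind!r}")
    return syn


# (duration s, rate Hz); the 10-s silent segment exercises the w_max clip
DEFAULT_SCHEDULE = ((10.0, 20.0), (10.0, 35.0), (10.0, 50.0),
                    (10.0, 0.0), (10.0, 40.0), (10.0, 25.0))


def _poisson_counts(u: np.ndarray, lam: float) -> np.ndarray:
    """Per-step spike counts from uniforms (series to O(lam^3))."""
    p0 = math.exp(-lam)
    p1 = p0 * (1.0 + lam)
    return (u >= p0).astype(np.float64) + (u >= p1)


def run_homeostasis_experiment(
    n_trials: int = 50,
    seed: int = 1,
    params: HomeoParams | None = None,
    fixed_rate: float = 50.0,
    w_static: float = 3.5,
    schedule=DEFAULT_SCHEDULE,
    kick_mv_per_na: float = 8.0,
    dt: float = 0.5,
    tau_m: float = 10.0,
    v_gap: float = 20.0,
    t_ref: float = 2.0,
    plastic: bool = True,
) -> dict:
    """Simulate the two-input homeostasis paradigm, vectorized over trials.

    The neuron is a leaky integrator with threshold ``v_gap`` mV above rest
    and reset to rest; each input spike deflects the membrane by
    ``weight * kick_mv_per_na`` mV.  Returns per-segment output rates, the
    mean output rate outside silent segments, and weight traces.

    With ``plastic=False`` the plastic weight is frozen at ``w_init`` and
    the output rate simply follows the varying input.
    """
    params = params or HomeoParams()
    rng_fix = NoiseStream((seed % 2**32, 0, 0, 0))
    rng_var = NoiseStream((seed % 2**32, 0, 1, 0))

    w = np.full(n_trials, params.w_init)
    v = np.zeros(n_trials)  # relative to rest
    ref = np.zeros(n_trials)  # remaining refractory steps
    decay = math.exp(-dt / tau_m)
    ref_steps = int(round(t_ref / dt))
    lam_fix = fixed_rate * dt / 1000.0

    seg_rates = []
    seg_is_silent = []
    w_trace = []
    for dur_s, rate in schedule:
        nsteps = int(round(dur_s * 1000.0 / dt))
        lam_var = rate * dt / 1000.0
        spikes_seg = np.zeros(n_trials)
        u_fix = rng_fix.uniforms(nsteps * n_trials).reshape(nsteps, n_trials)
        u_var = rng_var.uniforms(nsteps * n_trials).reshape(nsteps, n_trials)
        for k in range(nsteps):
            n_fix = _poisson_counts(u_fix[k], lam_fix)
            n_var = (_poisson_counts(u_var[k], lam_var)
                     if lam_var > 0 else 0.0)
            if plastic:
                w = np.minimum(np.maximum(
                    w + params.dw_plus * n_fix, 0.0), params.w_max)
            drive = (w * n_fix + w_static * n_var) * kick_mv_per_na
            active = ref <= 0
            v = np.where(active, v * decay + drive, 0.0)
            spiked = active & (v >= v_gap)
            spikes_seg += spiked
            v = np.where(spiked, 0.0, v)
            ref = np.where(spiked, ref_steps, ref - 1)
            if plastic:
                w = np.minimum(np.maximum(
                    w + params.dw_minus * spiked, 0.0), params.w_max)
        seg_rates.append(spikes_seg / dur_s)
        seg_is_silent.append(rate == 0.0)
        w_trace.append(w.copy())

    seg_rates = np.asarray(seg_rates)  # (n_segments, n_trials)
    nonsilent = ~np.asarray(seg_is_silent)
    durations = np.asarray([d for d, _ in schedule])
    wsum = durations[nonsilent] @ seg_rates[nonsilent] / durations[nonsilent].sum()
    return {
        "segment_rates": seg_rates,
        "segment_rates_mean": seg_rates.mean(axis=1),
        "silent": np.asarray(seg_is_silent),
        "rate_nonsilent": wsum,  # per trial
        "mean_rate_nonsilent": float(wsum.mean()),
        "weights_end": np.asarray(w_trace),
        "schedule": tuple(schedule),
    }
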