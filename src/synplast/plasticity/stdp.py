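"""Pair-based spike-timing-dependent plasticity.

Each synapse keeps two exponentially decaying eligibility traces, ``a_pre``
(incremented by presynaptic spikes, amplitude ``A_pre > 0``) and ``a_post``
(incremented by postsynaptic spikes, amplitude ``A_post < 0``).  The weight
is updated for each complete pre/post pair: on a presynaptic spike by the
current value of ``a_post``, on a postsynaptic spike by the current value
of ``a_pre``.  Trace decay between events is applied analytically, so
event-driven updates agree with dense-grid integration to machine
precision.

The weight's conductance contribution to the postsynaptic cell is clipped
at ``w_max``; the weight itself is clipped below at zero by default
(configurable).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

__all__ = ["StdpParams", "StdpSynapse", "stdp_on_spike", "stdp_window"]


@dataclass(frozen=True)
class StdpParams:
    """Amplitudes in uS, time constants in ms.

    The default set is the classical-curve parameterization; the detailed
    single-synapse analysis uses ``A_pre=0.3, A_post=-0.2, tau_post=10``.
    """

    a_pre: float = 0.01
    a_post: float = -0.0105
    tau_pre: float = 20.0
    tau_post: float = 20.0
    w0: float = 1.0
    w_max: float = 10.0
    clip_low: float | None = 0.0


@dataclass
class StdpSynapse:
    params: StdpParams = field(default_factory=StdpParams)
    w: float = None  # type: ignore[assignment]
    a_pre: float = 0.0
    a_post: float = 0.0
    t_last: float = -math.inf

    def __post_init__(self) -> None:
        if self.w is None:
            self.w = self.params.w0

    @property
    def conductance(self) -> float:
        """Contribution to the postsynaptic cell: ``min(w, w_max)``."""
        return min(self.w, self.params.w_max)

    def decay_to(self, t: float) -> None:
        if self.t_last == -math.inf:
            self.t_last = t
            return
        if t < self.t_last:
            raise ValueError(f"time regression: {t} < {self.t_last}")
        dt = t - self.t_last
        if dt > 0:
            self.a_pre *= math.exp(-dt / self.params.tau_pre)
            self.a_post *= math.exp(-dt / self.params.tau_post)
            self.t_last = t

    def on_pre_spike(self, t: float) -> None:
        self.decay_to(t)
        self.w += self.a_post
        self.a_pre += self.params.a_pre
        self._clip()

    def on_post_spike(self, t: float) -> None:
        self.decay_to(t)
        self.w += self.a_pre
        self.a_post += self.params.a_post
        self._clip()

    def _clip(self) -> None:
        lo = self.params.clip_low
        if lo is not None and self.w < lo:
            self.w = lo


def stdp_on_spike(syn: StdpSynapse, t: float, kind: str) -> StdpSynapse:
    """Apply one pre- or postsynaptic spike at time ``t`` (ms)."""
    if kind == "pre":
        syn.on_pre_spike(t)
    elif kind == "post":
        syn.on_post_spike(t)
    else:
        raise ValueError(f"kind must be 'pre' or 'post', got {kind!r}")
    return syn


def stdp_window(delta_t: float, params: StdpParams) -> float:
    """Weight change for one isolated pre/post pair at lag ``delta_t``.

    ``delta_t > 0`` means post follows pre (potentiation,
    ``A_pre * exp(-dt/tau_pre)``); ``delta_t < 0`` means pre follows post
    (depression, ``A_post * exp(dt/tau_post)``).  ``delta_t = 0`` is
    treated as an undecayed pre-then-post pair.
    """
    if delta_t >= 0:
        return params.a_pre * math.exp(-delta_t / params.tau_pre)
    return params.a_post * math.exp(delta_t / params.tau_post)
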