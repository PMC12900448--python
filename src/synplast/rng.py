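"""Counter-based random numbers and Euler-Maruyama SDE integration.

Every source of white noise in a simulation is a :class:`NoiseStream`,
identified by a hierarchical key ``(global seed, cell gid, mechanism id,
variable index)``.  Uniform variates are produced by a stateless
counter-based generator (Philox 4x64): the variates at a given
``(key, counter)`` are a pure function of that pair, across runs and
platforms.  This makes an entire simulation a pure function of its
configuration and seed, and lets independent noise sources be drawn
without any shared generator state.

Normal variates come from the Box-Muller transform, which consumes both
outputs of each uniform pair so that all streams deplete their caches at
the same rate (no rejection sampling).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "NoiseStream",
    "SdeSystem",
    "draw_uniforms",
    "draw_normal_pair",
    "euler_maruyama_step",
]

_U64 = np.uint64
_COUNTER_MAX = 2**64 - 1
# 2**-53: converts the top 53 bits of a uint64 into a double in [0, 1)
_INV_2_53 = 1.0 / 9007199254740992.0
# guard for Box-Muller at u1 == 0 (smallest positive subnormal double)
_TINY = 5e-324


class CounterOverflowError(RuntimeError):
    """Raised when a stream's 64-bit block counter would wrap around."""


class NoiseStream:
    """A stateless-keyed stream of uniform and normal variates.

    Parameters
    ----------
    key:
        Up to four non-negative integers, each below 2**32, conventionally
        ``(global seed, cell gid, mechanism id, variable index)``.  They are
        packed into the 128-bit Philox key, so distinct tuples give
        statistically independent streams.
    counter:
        Starting block index.  Block ``n`` always yields the same four
        uniforms for a given key.
    """

    def __init__(self, key: Sequence[int] | int, counter: int = 0):
        if isinstance(key, int):
            key = (key,)
        key = tuple(int(k) for k in key)
        if len(key) > 4 or any(k < 0 or k >= 2**32 for k in key):
            raise ValueError(
                "key must be up to 4 integers in [0, 2**32); got %r" % (key,)
            )
        padded = key + (0,) * (4 - len(key))
        self.key = key
        self._key128 = (
            _U64(padded[0] << 32 | padded[1]),
            _U64(padded[2] << 32 | padded[3]),
        )
        if counter < 0:
            raise ValueError("counter must be non-negative")
        self.counter = int(counter)
        self._cache: list[float] = []
        self._pending_normal: float | None = None

    # -- low-level block access -------------------------------------------

    def _raw_blocks(self, start: int, nblocks: int) -> np.ndarray:
        """Uniforms of blocks ``start .. start+nblocks-1`` (4 per block)."""
        if start + nblocks > _COUNTER_MAX:
            raise CounterOverflowError(
                f"stream {self.key}: counter would exceed 2**64-1"
            )
        bg = np.random.Philox(
            counter=np.array([start, 0, 0, 0], dtype=np.uint64),
            key=np.array(self._key128, dtype=np.uint64),
        )
        raw = bg.random_raw(4 * nblocks)
        return (raw >> _U64(11)).astype(np.float64) * _INV_2_53

    def draw_block(self) -> tuple[float, float, float, float]:
        """One generator invocation: exactly four uniforms in [0, 1).

        Refreshes the cache (advancing the counter by exactly one) and
        returns the four fresh values.
        """
        vals = self._raw_blocks(self.counter, 1)
        self.counter += 1
        self._cache = list(vals)
        return tuple(self._cache)  # type: ignore[return-value]

    # -- scalar draws ------------------------------------------------------

    def uniform(self) -> float:
        """Next uniform variate in [0, 1); refills the cache on depletion."""
        if not self._cache:
            self.draw_block()
        return self._cache.pop(0)

    def normal(self) -> float:
        """Next standard-normal variate (Box-Muller, both outputs used)."""
        if self._pending_normal is not None:
            z = self._pending_normal
            self._pending_normal = None
            return z
        z1, z2 = draw_normal_pair(self.uniform(), self.uniform())
        self._pending_normal = z2
        return z1

    # -- bulk draws --------------------------------------------------------

    def uniforms(self, n: int) -> np.ndarray:
        """``n`` uniforms, drawn block-aligned; leftovers are cached."""
        if n < 0:
            raise ValueError("n must be non-negative")
        out = np.empty(n)
        m = min(n, len(self._cache))
        out[:m] = self._cache[:m]
        del self._cache[:m]
        need = n - m
        if need:
            nblocks = -(-need // 4)
            vals = self._raw_blocks(self.counter, nblocks)
            self.counter += nblocks
            out[m:] = vals[:need]
            self._cache = list(vals[need:])
        return out

    def normals(self, n: int) -> np.ndarray:
        """``n`` standard normals via vectorized Box-Muller."""
        if n < 0:
            raise ValueError("n must be non-negative")
        out = np.empty(n)
        m = 0
        if self._pending_normal is not None and n > 0:
            out[0] = self._pending_normal
            self._pending_normal = None
            m = 1
        need = n - m
        if need:
            npairs = -(-need // 2)
            u = self.uniforms(2 * npairs)
            u1 = np.where(u[0::2] == 0.0, _TINY, u[0::2])
            r = np.sqrt(-2.0 * np.log(u1))
            ang = 2.0 * np.pi * u[1::2]
            z = np.empty(2 * npairs)
            z[0::2] = r * np.cos(ang)
            z[1::2] = r * np.sin(ang)
            out[m:] = z[:need]
            if 2 * npairs > need:
                self._pending_normal = float(z[need])
        return out

    def __repr__(self) -> str:  # pragma: no cover
        return f"NoiseStream(key={self.key}, counter={self.counter})"


def draw_uniforms(stream: NoiseStream) -> tuple[float, float, float, float]:
    """Four uniform variates from one generator invocation of ``stream``."""
    return stream.draw_block()


def draw_normal_pair(u1: float, u2: float) -> tuple[float, float]:
    """Box-Muller transform of two uniforms into two standard normals.

    ``z1 = sqrt(-2 ln u1) cos(2 pi u2)``, ``z2 = sqrt(-2 ln u1) sin(2 pi u2)``.
    ``u1 == 0`` is guarded by substituting the smallest positive double.
    """
    if u1 == 0.0:
        u1 = _TINY
    r = math.sqrt(-2.0 * math.log(u1))
    return r * math.cos(2.0 * math.pi * u2), r * math.sin(2.0 * math.pi * u2)


@dataclass
class SdeSystem:
    """State and coefficients of ``dX = f dt + sum_i g_i dB_i``.

    ``drift`` maps ``(t, X) -> dX/dt`` and each diffusion maps
    ``(t, X) -> g_i(t, X)``; the Wiener increments are mutually independent
    (identity correlation matrix).  One :class:`NoiseStream` per Wiener
    process.  With all diffusions absent or zero the step reduces exactly to
    deterministic forward Euler.
    """

    state: np.ndarray
    drift: Callable[[float, np.ndarray], np.ndarray]
    diffusions: Sequence[Callable[[float, np.ndarray], np.ndarray]] = field(
        default_factory=tuple
    )
    streams: Sequence[NoiseStream] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        self.state = np.atleast_1d(np.asarray(self.state, dtype=float))
        if len(self.diffusions) != len(self.streams):
            raise ValueError(
                f"{len(self.diffusions)} diffusion functions but "
                f"{len(self.streams)} noise streams"
            )


def euler_maruyama_step(system: SdeSystem, t: float, dt: float) -> np.ndarray:
    """Advance ``system.state`` by one Euler-Maruyama step of size ``dt``.

    ``X(t+dt) = X + f(t, X) dt + sum_i g_i(t, X) dW_i`` with
    ``dW_i ~ N(0, dt)`` independent.  Returns the updated state (also stored
    on the system).
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    x = system.state
    fx = np.asarray(system.drift(t, x), dtype=float)
    if not np.all(np.isfinite(fx)):
        raise FloatingPointError("non-finite drift evaluation")
    new = x + fx * dt
    sqdt = math.sqrt(dt)
    for i, (g, stream) in enumerate(zip(system.diffusions, system.streams)):
        gx = np.asarray(g(t, x), dtype=float)
        if not np.all(np.isfinite(gx)):
            raise FloatingPointError(f"non-finite diffusion evaluation (g_{i})")
        new = new + gx * (stream.normal() * sqdt)
    system.state = new
    return new
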