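"""Brute-force dense-grid oracles used by the test suite.

These integrate the weight dynamics on a uniform fine grid with explicit
Euler, independently of the package's event-driven window integrators.
They are compiled with numba because the reference grids are 100x finer
than the simulation grid.
"""

import math

import numpy as np
from numba import njit


@njit(cache=False)
def gb_dense_euler(ev_t, ev_a, dt, t_end, w0, tau_c, tau_w, gamma_p,
                   gamma_d, theta_p, theta_d, w_star):
    """Bistable calcium rule, noise off, impulses (ev_t, ev_a) on calcium."""
    n = int(t_end / dt)
    c = 0.0
    w = w0
    idx = 0
    dec = math.exp(-dt / tau_c)
    for k in range(n):
        hp = 1.0 if c >= theta_p else 0.0
        hd = 1.0 if c >= theta_d else 0.0
        w += (-w * (1 - w) * (w_star - w) + gamma_p * (1 - w) * hp
              - gamma_d * w * hd) / tau_w * dt
        c *= dec
        t_next = (k + 1) * dt
        while idx < len(ev_t) and ev_t[idx] <= t_next:
            c += ev_a[idx] * math.exp(-(t_next - ev_t[idx]) / tau_c)
            idx += 1
    return w


@njit(cache=False)
def stc_dense_euler(ev_t, ev_a, dt, t_end, h0, tau_c, tau_h, gamma_p,
                    gamma_d, theta_p, theta_d, h_max):
    """Early-phase weight of the tagging-and-capture rule, noise off."""
    n = int(t_end / dt)
    c = 0.0
    h = h0
    idx = 0
    dec = math.exp(-dt / tau_c)
    for k in range(n):
        hp = 1.0 if c >= theta_p else 0.0
        hd = 1.0 if c >= theta_d else 0.0
        h += (0.1 * (h0 - h) + gamma_p * (h_max - h) * hp
              - gamma_d * h * hd) / tau_h * dt
        if h < 0.0:
            h = 0.0
        elif h > h_max:
            h = h_max
        c *= dec
        t_next = (k + 1) * dt
        while idx < len(ev_t) and ev_t[idx] <= t_next:
            c += ev_a[idx] * math.exp(-(t_next - ev_t[idx]) / tau_c)
            idx += 1
    return h
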