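"""Implicit time-stepping of membrane voltage and particle diffusion.

Both the cable equation (membrane potential on a branched neurite) and the
diffusion of a neutral particle species have the same spatial structure on
the compartment tree, so both are advanced with the same unconditionally
stable backward-Euler scheme.  The tree matrix is factorized once (scipy
sparse LU) and reused whenever the coefficients are static; with
voltage-dependent channels (Hodgkin-Huxley) the gating variables are
advanced by their exact exponential update and the matrix is reassembled
each step.

Internal units: time ms, length um, voltage mV, current nA, conductance uS,
capacitance nF, concentration umol/l.  Diffusivities are accepted in m^2/s
and converted once at construction (1 m^2/s = 1e9 um^2/ms).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .morphology import CompartmentGrid

__all__ = [
    "MembraneState",
    "SpeciesField",
    "HodgkinHuxley",
    "step_voltage",
    "step_diffusion",
    "total_amount",
    "M2_PER_S_TO_UM2_PER_MS",
    "UF_PER_CM2_TO_NF_PER_UM2",
    "MS_PER_CM2_TO_US_PER_UM2",
    "OHM_CM_TO_MOHM_UM",
]

M2_PER_S_TO_UM2_PER_MS = 1e9
UF_PER_CM2_TO_NF_PER_UM2 = 1e-5
MS_PER_CM2_TO_US_PER_UM2 = 1e-5
OHM_CM_TO_MOHM_UM = 1e-2


def _tree_laplacian(grid: CompartmentGrid, coupling: np.ndarray) -> sp.csc_matrix:
    """Symmetric flux matrix from per-compartment parent couplings.

    ``coupling[i]`` couples compartment ``i`` to its parent; the root entry
    is ignored.  Row sums are zero, so any quantity advanced with this
    operator is conserved across the tree.
    """
    n = grid.n
    rows, cols, vals = [], [], []
    for i in range(n):
        p = grid.parent[i]
        if p < 0:
            continue
        g = coupling[i]
        rows += [i, p, i, p]
        cols += [i, p, p, i]
        vals += [g, g, -g, -g]
    return sp.csc_matrix((vals, (rows, cols)), shape=(n, n))


# ---------------------------------------------------------------------------
# Voltage

class HodgkinHuxley:
    """Classic squid-axon sodium/potassium channels on a set of compartments.

    The rate functions are the standard ones (resting potential near
    -65 mV); conductance densities in mS/cm^2, reversal potentials in mV.
    Gating variables are advanced with the exact exponential update
    ``x <- x_inf + (x - x_inf) exp(-dt/tau_x)`` evaluated at the current
    voltage.
    """

    def __init__(self, compartments: np.ndarray,
                 gna: float = 120.0, gk: float = 36.0, gl: float = 0.3,
                 ena: float = 50.0, ek: float = -77.0, el: float = -54.387):
        self.comps = np.asarray(compartments, dtype=np.int64)
        self.gna, self.gk, self.gl = gna, gk, gl
        self.ena, self.ek, self.el = ena, ek, el
        self.m = None  # initialized at first step from resting voltage
        self.h = None
        self.n = None

    @staticmethod
    def _rates(v: np.ndarray):
        def vtrap(x, y):
            # x / (1 - exp(-x/y)) with the removable singularity handled
            small = np.abs(x / y) < 1e-6
            return np.where(small, y * (1 + x / y / 2), x / (1 - np.exp(-x / y)))

        am = 0.1 * vtrap(v + 40.0, 10.0)
        bm = 4.0 * np.exp(-(v + 65.0) / 18.0)
        ah = 0.07 * np.exp(-(v + 65.0) / 20.0)
        bh = 1.0 / (1.0 + np.exp(-(v + 35.0) / 10.0))
        an = 0.01 * vtrap(v + 55.0, 10.0)
        bn = 0.125 * np.exp(-(v + 65.0) / 80.0)
        return am, bm, ah, bh, an, bn

    def init_gates(self, v: np.ndarray) -> None:
        am, bm, ah, bh, an, bn = self._rates(v[self.comps])
        self.m = am / (am + bm)
        self.h = ah / (ah + bh)
        self.n = an / (an + bn)

    def advance_gates(self, v: np.ndarray, dt: float) -> None:
        if self.m is None:
            self.init_gates(v)
        am, bm, ah, bh, an, bn = self._rates(v[self.comps])
        for x, a, b in ((self.m, am, bm), (self.h, ah, bh), (self.n, an, bn)):
            tau = 1.0 / (a + b)
            xinf = a * tau
            x += (xinf - x) * -np.expm1(-dt / tau)

    def conductances(self, area_lateral: np.ndarray):
        """Per-compartment (g, g*E) contributions in uS and uS*mV."""
        a = area_lateral[self.comps] * MS_PER_CM2_TO_US_PER_UM2
        gna = self.gna * a * self.m**3 * self.h
        gk = self.gk * a * self.n**4
        gl = self.gl * a
        g = gna + gk + gl
        ge = gna * self.ena + gk * self.ek + gl * self.el
        return self.comps, g, ge


@dataclass
class MembraneState:
    """Membrane potential and passive/channel parameters on a grid.

    ``c_m`` in uF/cm^2, ``r_l`` (axial resistivity) in Ohm*cm, ``g_leak``
    in mS/cm^2, potentials in mV.  ``hh`` optionally adds Hodgkin-Huxley
    channels to a subset of compartments (the leak is then usually set to
    zero there via the channel's own leak).
    """

    grid: CompartmentGrid
    v: np.ndarray = None  # type: ignore[assignment]
    c_m: float = 1.0
    r_l: float = 100.0
    g_leak: float = 0.1
    e_leak: float = -65.0
    hh: Optional[HodgkinHuxley] = None
    _lu: object = field(default=None, repr=False)
    _lu_key: tuple = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.v is None:
            self.v = np.full(self.grid.n, self.e_leak, dtype=float)
        self.v = np.asarray(self.v, dtype=float)
        g = self.grid
        self.cap = self.c_m * UF_PER_CM2_TO_NF_PER_UM2 * g.area_lateral
        rl = self.r_l * OHM_CM_TO_MOHM_UM
        with np.errstate(divide="ignore"):
            ax = np.where(g.parent >= 0, g.a_face / (rl * g.dist), 0.0)
        if np.any((g.parent >= 0) & ~np.isfinite(ax)):
            raise ValueError("degenerate geometry: singular axial coupling")
        self.g_axial = ax
        self._lap = _tree_laplacian(g, ax)
        self.g_leak_comp = (self.g_leak * MS_PER_CM2_TO_US_PER_UM2
                            * g.area_lateral)


def step_voltage(state: MembraneState, grid: CompartmentGrid,
                 stimuli: Optional[np.ndarray], dt: float) -> MembraneState:
    """One backward-Euler step of the cable equation on the whole tree.

    ``stimuli`` is a per-compartment injected current in nA (or None).
    Channel conductances are frozen at their start-of-step values inside
    the implicit solve, which keeps the scheme unconditionally stable.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if grid is not state.grid:
        raise ValueError("state and grid do not match")
    n = grid.n
    g_tot = state.g_leak_comp.copy()
    ge = state.g_leak_comp * state.e_leak
    if state.hh is not None:
        state.hh.advance_gates(state.v, dt)
        comps, g, gev = state.hh.conductances(grid.area_lateral)
        g_tot[comps] += g
        ge[comps] += gev
    rhs = state.cap / dt * state.v + ge
    if stimuli is not None:
        rhs = rhs + stimuli
    if state.hh is None and state._lu is not None and state._lu_key == dt:
        lu = state._lu
    else:
        a = state._lap + sp.diags(state.cap / dt + g_tot, format="csc")
        try:
            lu = spla.splu(a.tocsc())
        except RuntimeError as exc:  # singular factorization
            raise ValueError(f"singular cable system: {exc}") from None
        if state.hh is None:
            state._lu, state._lu_key = lu, dt
    state.v = lu.solve(rhs)
    return state


# ---------------------------------------------------------------------------
# Diffusion

@dataclass
class SpeciesField:
    """Concentration of one neutral particle species on a grid.

    ``diffusivity`` in m^2/s (converted internally), optional linear decay
    with time constant ``tau`` (ms), per-compartment source ``source`` in
    concentration per ms.  The species carries no charge and is fully
    decoupled from the membrane potential.
    """

    name: str
    grid: CompartmentGrid
    conc: np.ndarray = None  # type: ignore[assignment]
    diffusivity: float = 0.0
    tau: Optional[float] = None
    source: np.ndarray = None  # type: ignore[assignment]
    _lu: object = field(default=None, repr=False)
    _lu_key: tuple = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.diffusivity < 0:
            raise ValueError("diffusivity must be non-negative")
        if self.conc is None:
            self.conc = np.zeros(self.grid.n)
        self.conc = np.asarray(self.conc, dtype=float)
        if self.source is None:
            self.source = np.zeros(self.grid.n)
        self.d_um = self.diffusivity * M2_PER_S_TO_UM2_PER_MS


def step_diffusion(field: SpeciesField, grid: CompartmentGrid,
                   dt: float) -> SpeciesField:
    """One implicit step of diffusion + decay + sources, sealed boundaries.

    The update is conservative: with no decay and zero sources the total
    amount ``sum_i c_i V_i`` is preserved to solver precision.  Decay and
    sources are treated implicitly/explicitly so that the total amount
    follows the exact discrete balance
    ``M' = (M + dt * sum_i V_i phi_i) / (1 + dt/tau)``.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if grid is not field.grid:
        raise ValueError("field and grid do not match")
    key = (dt, field.d_um, field.tau)
    if field._lu is None or field._lu_key != key:
        with np.errstate(divide="ignore"):
            coup = np.where(grid.parent >= 0,
                            field.d_um * grid.a_face / grid.dist, 0.0)
        a = _tree_laplacian(grid, coup) + sp.diags(grid.volume / dt)
        if field.tau is not None:
            a = a + sp.diags(grid.volume / field.tau)
        field._lu = spla.splu(a.tocsc())
        field._lu_key = key
    rhs = grid.volume * (field.conc / dt + field.source)
    field.conc = field._lu.solve(rhs)
    if np.any(field.conc < -1e-12):
        # only possible with negative sources; clip tiny negative noise
        field.conc = np.maximum(field.conc, 0.0)
    return field


def total_amount(field: SpeciesField, grid: CompartmentGrid) -> float:
    """Total amount ``sum_i c_i V_i`` in (umol/l) * um^3.

    Divide by 1e15 to obtain umol (1 litre = 1e15 um^3); the raw product is
    what the concentration-threshold renormalization uses.
    """
    if field.conc.shape[0] != grid.n:
        raise ValueError("field and grid sizes do not match")
    return float(np.dot(field.conc, grid.volume))
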