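# Methods

`synplast` simulates spike-driven synaptic plasticity at three scales:
single synapses, diffusion-coupled dendritic compartments, and recurrent
spiking networks.  This note documents the models, the numerical choices,
and the places where the design was genuinely open.

## Random numbers and stochastic integration

Every white-noise source is a `NoiseStream` identified by a hierarchical
key `(global seed, cell gid, mechanism id, variable index)` and a block
counter.  The generator is Philox 4x64 (a counter-based bijection with a
128-bit key): the four uniforms of block *n* are a pure function of
`(key, n)`, so a whole simulation is a pure function of its configuration
and seed, streams never share state, and re-running any phase reproduces
it bitwise.  The cache of four uniforms is refreshed only on depletion;
counter overflow is a hard error, never a silent wrap.  Normal variates
use the Box–Muller transform with both outputs consumed, so all streams
deplete at the same rate; `u1 = 0` is guarded by substituting the
smallest positive double.

Stochastic differential equations `dX = f dt + Σ g_i dB_i` are integrated
with Euler–Maruyama: `ΔW_i ~ N(0, dt)` drawn one per diffusion term and
step (uncorrelated noise only).  With all diffusions zero the step reduces
exactly to forward Euler.  Gaussian white noise written as `Γ(t)` with
variance `1/dt` is realized as `ΔW/dt`, so a term `g·Γ·dt` contributes
`g·ΔW` per step.

## Cable and particle diffusion on branched morphologies

Morphologies are trees of tapered cylinders (read/written as standard
7-column SWC); discretization splits each segment into `ceil(L/Δl)`
equal-length compartments whose frustum volumes sum exactly to the
segment volume.  Both the cable equation for the membrane potential and
the diffusion equation for neutral particle species share the same tree
structure and are advanced with backward Euler (unconditionally stable);
the sparse tree system is LU-factorized once and reused whenever the
coefficients are static.  Boundaries are sealed: with zero sources and no
decay the total amount `Σ c_i V_i` is conserved to solver precision
(~1e-12 relative).  Decay and sources enter the implicit step so that the
total amount obeys the exact discrete balance
`M' = (M + dt·ΣV_i φ_i)/(1 + dt/τ)`; tests exploit this identity.
Diffusing species carry no charge and are fully decoupled from the
voltage; Nernst-style feedback is deliberately not implemented.

Units: lengths um, time ms, voltage mV, current nA, conductance uS,
concentration umol/l.  Diffusivities are accepted in m²/s and converted
once (1 m²/s = 1e9 um²/ms).

Hodgkin–Huxley channels (standard squid-axon rate functions, resting
potential near −65 mV) can be attached to compartments; gating variables
use the exact exponential update at the current voltage, and the voltage
matrix is refactorized per step in that case.

## Plasticity rules

**Pair-based STDP.**  Eligibility traces `a_pre`, `a_post` decay
analytically between events, so event-driven updates equal dense-grid
integration to machine precision.  On a presynaptic spike the weight
changes by the current `a_post` (and vice versa): only complete pairs
move the weight.  The conductance contribution is clipped at `w_max`; the
weight itself is clipped below at zero by default (configurable), since
only the upper clip is prescribed.

**Spike-driven homeostasis.**  `w += Δw⁺` per presynaptic and
`w += Δw⁻` per postsynaptic spike, clipped to `[0, w_max]`.  With
`Δw⁺ = |Δw⁻|` the weight is stationary only when output rate equals the
plastic input's rate, so the neuron's rate is regulated to 50 Hz (the
fixed input rate).  The paradigm uses current-based delta synapses with a
kick of `weight × 8 mV/nA`, a 20-mV threshold gap, τ_m = 10 ms, 2-ms
refractoriness, and a varying-rate schedule (20/35/50/0/40/25 Hz, 10 s
each); these constants are this package's documented defaults — chosen so
the 50-Hz set point is reachable with `w ≤ w_max` at every nonzero
schedule rate — and are configuration, not printed values.

**Bistable calcium rule.**  The weight relaxes in a double-well potential
(`w* = 0.5`) with calcium-gated potentiation/depression and
activity-gated noise.  Calcium is a leaky integrator of the spike trains
with the presynaptic influx delayed by `t_c,delay`; because it never
depends on the weight, supra-threshold windows are computed analytically
and fine Euler–Maruyama steps are spent only inside them (outside, only
the deterministic cubic drift acts and is integrated coarsely).  The
noise prefactor is implemented as `σ_pl √(τ (Θ_p + Θ_d))` (the form of
the underlying model family); a `literal_printed_noise` flag switches to
the τ(Θ_p+Θ_d)σ_pl variant for sensitivity checks.  The pairing-curve
observable is the trial mean of `w_end − w_start` with `w₀ ~ Bernoulli(½)`
on {0, 1}; at the standard 60-pair/1-Hz protocol the depression trough
(mean ≈ −0.03 at Δt = −10 ms) needs the full 4000 trials to stand out of
the trial noise, which the window integrator delivers in seconds.

**Heterosynaptic calcium-diffusion rule.**  Four one-compartment spines
(r = l = 1 um) sit at −1, 0, +1, +3 um around the midpoint of an 80-um
dendrite.  Active spines inject a calcium-carrying current
`w_i Σ I₀ e^{−(t−t_j)/τ_I}` converted to a concentration flux by the
calcium fraction γ and the head volume; the field diffuses
(D = 2.2e−10 m²/s) and decays (τ_C = 100 ms), and each spine's weight
follows the threshold rule at its local concentration.  The injected
amount per spike integrates exactly to `γ I₀ τ_I / 2F` because the source
is window-averaged over each step.  The injection amplitude is
implementation-dependent (published implementations use 4.0–5.5 pA with
distinct spine-exchange rate factors); with this package's fully
diffusive spine coupling the default is 0.75 pA, which places the
active-spine calcium just above θ_p and the remote spine between θ_d and
θ_p.  With the steady-state decay length `λ = √(D τ_C) ≈ 4.7 um`, the
printed geometry yields roughly a 2.2× concentration contrast between
stimulated and remote spines — exactly the ratio of the two thresholds.
The initial spine weight (0.5) is a configuration default.

**Synaptic tagging and capture.**  The total weight is `w = h + h₀ z`.
The early phase `h` follows the bistable calcium rule (drift toward `h₀`
plus gated potentiation toward 10 mV / depression toward 0, noise gated
by the thresholds, clipped to [0, 10 mV] under noise).  A synapse is
tagged while `|h − h₀| > θ_tag`; the neuron synthesizes PRPs
(`τ_p dp/dt = −p + p_max Θ[Σ|h−h₀| − θ_pro]`, exact exponential update)
while the summed early-phase change of its synapses exceeds θ_pro; the
late phase `z` grows toward 1 (or decays toward −0.5) at a rate
proportional to the local PRP concentration.  Integration is hybrid:
full-detail Euler–Maruyama inside the analytic supra-θ_d calcium
windows, exact exponential relaxation of `h` plus a coarse (10-s)
"fast-forward" grid for `z` and `p` elsewhere.  This is not an
approximation: drift and noise of `h` vanish identically when calcium is
below θ_d.

The classical induction protocols are configuration presets: STET
(3 × 100 Hz for 1 s, 10 min apart), WTET (100 Hz, 0.2 s), SLFS (900
bursts of 3 spikes at 20 Hz, at 1 Hz), WLFS (900 single pulses at 1 Hz).
Pathway stimulation evokes a postsynaptic spike at 10-ms latency with
probability 0.5 on top of 0.2-Hz spontaneous firing; without this
co-activation, single low-frequency pulses (calcium amplitude 1.0,
θ_d = 1.2) can never cross the depression threshold and WLFS would be
inert.  End-of-protocol states are read 5 s after the last pulse; late
phases are measured at 8 h via fast-forward.

## Recurrent memory networks

The network has 500 leaky integrate-and-fire neurons (400 excitatory,
100 inhibitory), Bernoulli connectivity p = 0.1 without self-connections,
plastic synapses only among excitatory neurons (in-vivo calcium
correction 0.6 applied), and static delta synapses elsewhere, all with a
3-ms delay.  Within a timestep (0.5 ms) the order is fixed: deliver due
events → integrate membranes → detect spikes (registered at step end) →
post-spike dispatch → plasticity updates.  Background drive is an OU-type
mean depolarization (6.5 mV) plus white noise (0.85 mV/√ms) integrated
exactly; all per-step randomness is keyed by the step index, so a run
split into phases at any boundary reproduces the unsplit raster
bit-for-bit (in-flight events persist across contiguous full phases and
are dropped by non-empty fast-forward phases, which freeze spiking).

A plastic kick deflects the postsynaptic membrane by
`(h + h₀ z) × syn_gain` with `syn_gain = 0.2`, representing the charge
transfer of a brief current-based synapse relative to an instantaneous
jump.  The static weights (E→I 1.05 mV, I→E and I→I −6.3 mV) and the
background were chosen once so that the baseline excitatory rate is a
few Hz and the learning stimulus (Poisson 900 Hz × 2 mV for 1 s) drives
the 60-neuron assembly at ~90–100 Hz — the selectivity window in which
within-assembly calcium (pre + post contributions) crosses θ_p while
outgoing-synapse calcium (pre only) does not.  Recall stimulates half the
assembly for 0.5 s starting 10 s after learning; Q is computed from the
subpopulation rates in the 0.5-s window centered 100 ms after recall
onset (window centers shift with the compressed schedule; the window
length stays 0.5 s).  A deliberate deviation: scaling all synaptic
weights by N_full/N_reduced = 4 was tried and rejected — with delta
synapses it pushes single EPSPs past the threshold gap and the network
saturates; the reduced network instead keeps the kicks unscaled
(`weight_scale` remains available).

At this scale the trial-mean Q is ≈ +0.04 (10 seeds) with learning and
≈ 0 without; Q grows from assembly size 30 to 60 (7.5% to 15% of the
excitatory population, matching the relative assembly sizes of the
full-scale paradigm).  For assemblies ≥ 100 the reduced network leaves
the selectivity window (recurrent drive pushes the learning rate past
~100 Hz, so outgoing synapses potentiate as well) and the trend inverts —
a scaling artifact of the small network, not a property of the rule.

**Morphological variant.**  Excitatory cells become five-segment
cells: two soma cylinders with a PRP-synthesis compartment between them,
plus apical (external input) and basal (recurrent input) branches;
inhibition targets the soma.  The passive membrane is advanced implicitly
on the shared compartment tree (one factorization, all cells as
right-hand sides).  Synaptic kicks deposit the charge that equalizes to
the nominal deflection; at these geometries the cells are electrotonically
compact, so the dendrite-length effect on recall is carried by the
printed morphology-correction factors c_morpho (long < short), which
multiply the recurrent strength.  The consolidation signals diffuse:
synapses inject SPS at their compartment at rate `|h−h₀|/τ_sps`
(τ_sps = 1 s, so the total SPS amount tracks `Σ|h−h₀|` in the
instantaneous-mixing limit, and with D_sps = 1e−11 m²/s mixing across the
≤48-um cell takes ~0.1 s); while the somatic SPS *concentration* exceeds
the volume-renormalized threshold `θ_pro* = θ_pro/ΣV_i`, PRP is produced
in the synthesis compartment at a rate that reproduces the scalar pool
equation in the mixing limit, and diffuses with D_p.  A one-compartment
cell reduces exactly to the scalar PRP pool.  With D_p = 1e−19 m²/s the
dendrite tips stay below 1% of p_max over 8 h (no late phase); with
1e−11 m²/s the cell floods and recall statistics match the
single-compartment model within the seed-to-seed confidence band.

## Busyring benchmark

Rings of k = 4 neurons with 5-ms, suprathreshold connections propagate
one externally injected spike forever, so each neuron fires at
`1/(k t_delay)` = 50 Hz (delivery is tolerant to half a step of
floating-point drift, keeping the propagation exactly periodic after the
first lap).  Each cell additionally sends `s` zero-weight connections to
random endpoints; they load the event queue but cannot move any
membrane, so the raster is invariant — also when the zero-weight synapses
carry STDP state, whose traces evolve with the traffic while the
delivered amplitude stays the connection weight (zero).  The default
benchmark cell is a point neuron (which makes the exact-rate property
testable); a "simple-branchy" morphological cell (random per-cell
dendritic tree, Hodgkin–Huxley soma) is provided for single-cell use.

## Problem sizes and what the tests show

The bundled experiments run at desk scale: 50 homeostasis trials of 60 s,
4000 pairing-curve trials (via the window integrator), 10 protocol trials
with 8-h fast-forward, 10 network seeds of ~14 s simulated time, 6 s of
the four-spine experiment.  Synthetic inputs are Poisson or regular spike
trains; real recordings have rate nonstationarities, correlations and
dendritic nonlinearities that these generators do not emulate, so passing
tests certify the solvers and rules, not biological fidelity beyond the
models' own assumptions.  Known limitations: no correlated noise
(Q ≠ I), no Heun/higher-order SDE solvers, no ion-specific reversal
feedback, no structural or short-term plasticity, and the reduced
networks exhibit the full-scale trends only within the regimes described
above.
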