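# synplast

A self-contained simulator for **spike-driven synaptic plasticity** — from
single synapses, through diffusion-coupled dendritic compartments, to
recurrent spiking networks that form, consolidate and recall memories.
It is aimed at computational neuroscientists who want reproducible,
desk-scale implementations of the standard plasticity model families and
of the numerical machinery they need (counter-based noise streams,
stochastic integration, implicit cable/diffusion solvers on branched
morphologies).

## What it implements

* **Counter-based RNG + Euler–Maruyama** — every noise source is a
  stateless stream keyed by `(seed, cell, mechanism, variable)`; SDEs
  `dX = f dt + Σ gᵢ dBᵢ` integrate with `ΔWᵢ ~ N(0, dt)`, and normals come
  from Box–Muller.  Simulations are pure functions of (config, seed).
* **Cable & diffusion solver** — backward Euler on the compartment tree
  for both the membrane equation
  `C_m ∂U/∂t = ∂/∂x (1/R_l) ∂U/∂x + I_m` and neutral-particle diffusion
  `∂X/∂t = ∂/∂x D ∂X/∂x + φ` (sealed ends, exact mass balance), with
  optional Hodgkin–Huxley channels and SWC morphology input/output.
* **Five plasticity rule families**
  * pair-based STDP with analytic eligibility traces
    (`Δw = A_pre e^{−Δt/τ_pre}` for post-after-pre),
  * spike-driven homeostasis (`w += Δw⁺` per pre, `Δw⁻` per post spike),
  * the bistable calcium rule
    `τ_w dw/dt = −w(1−w)(w*−w) + γ_p(1−w)Θ[c−θ_p] − γ_d w Θ[c−θ_d] + ξ`,
  * heterosynaptic plasticity via calcium diffusing along a spiny
    dendrite,
  * synaptic tagging and capture: total weight `w = h + h₀z` with a
    calcium-driven early phase, tag threshold `θ_tag`, neuron-level PRP
    synthesis above `θ_pro`, and PRP-gated late phase.
* **Network experiments** — recurrent LIF networks (plastic E→E
  synapses), learning/recall stimulation, full and fast-forward
  simulation phases, the pattern-completion coefficient
  `Q = (ν̄_ans − ν̄_ctrl)/ν̄_as`, morphological-cell variants with
  diffusing SPS/PRP consolidation signals and the volume-renormalized
  threshold `θ_pro* = θ_pro/ΣVᵢ`, and the busyring event-delivery
  benchmark.

See `docs/methods.md` for the models, units, numerical choices and known
limitations.

## Worked example

Run the four classical induction protocols at a single synapse (strong
and weak tetanic / low-frequency stimulation), 3 trials, late phase
measured after a fast-forwarded 8 h:

```bash
synplast stc-protocols --seed 1 --trials 3 --out out/
cat out/summary.json
```

```json
{
  "STET": {"h_end_mv": 4.274, "z_end": 0.767, "w_end_mv": 7.495,
           "tag_crossed_frac": 1.0, "pro_crossed_frac": 1.0},
  "WTET": {"h_end_mv": 4.225, "z_end": 0.0,   "w_end_mv": 4.225,
           "tag_crossed_frac": 1.0, "pro_crossed_frac": 0.0},
  "SLFS": {"h_end_mv": 4.129, "z_end": -0.377, "w_end_mv": 2.547,
           "tag_crossed_frac": 1.0, "pro_crossed_frac": 1.0},
  "WLFS": {"h_end_mv": 4.181, "z_end": 0.0,   "w_end_mv": 4.181,
           "tag_crossed_frac": 1.0, "pro_crossed_frac": 0.0}
}
```

Reading this: every protocol moves the early-phase weight enough to set
the synaptic tag (`tag_crossed`), but only the *strong* protocols cross
the protein-synthesis threshold (`pro_crossed`) and therefore change the
late-phase weight `z` — upward for strong tetanic stimulation
(`z ≈ 0.77`: late-phase potentiation, total weight 7.5 mV vs the
4.2-mV baseline), downward for strong low-frequency stimulation
(`z ≈ −0.38`: late-phase depression).  The weak protocols leave `z ≈ 0`:
early-phase-only changes that decay back toward baseline by 8 h.

Other subcommands: `stdp-single`, `stdp-curve`, `homeostasis`,
`gb-curve`, `hetero`, `stc-single`, `stc-network`, `morpho-network`,
`busyring` — each with `--config --seed --trials --out`, bundled presets
in `src/synplast/presets/`, and plain-text raster/CSV/JSON outputs plus a
run manifest.

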