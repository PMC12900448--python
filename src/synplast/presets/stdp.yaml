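# Pair-based STDP; the classical-curve parameter set.  The alternative
# detailed-analysis set uses a_pre_us: 0.3, a_post_us: -0.2, tau_post_ms: 10.
experiment: stdp-curve
seed: 1
stdp:
  w0_us: 1.0
  tau_pre_ms: 20.0
  tau_post_ms: 20.0
  a_pre_us: 0.01
  a_post_us: -0.0105
  w_max_us: 10.0
curve:
  dt_min_ms: -100.0
  dt_max_ms: 100.0
  n_points: 41
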