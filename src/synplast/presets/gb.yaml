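# Bistable calcium-based plasticity (hippocampal-slice parameter set);
# weights and calcium are dimensionless.
experiment: gb-curve
seed: 1
trials: 400
gb:
  w_star: 0.5
  tc_delay_ms: 13.7
  c_pre: 1.0
  c_post: 2.0
  tau_c_ms: 20.0
  tau_w_s: 150.0
  gamma_p: 321.808
  gamma_d: 200.0
  theta_p: 1.3
  theta_d: 1.0
  sigma_pl: 2.8248
protocol:
  n_pairs: 60
  pair_rate_hz: 1.0
  dt_grid_ms: [-50, -30, -20, -10, -5, 0, 5, 10, 20, 30, 50]
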