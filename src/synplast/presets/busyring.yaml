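# Busyring event-delivery benchmark: rings of k neurons propagating one
# spike forever, plus s zero-weight random connections per cell.
experiment: busyring
seed: 1
busyring:
  n_cells: 16
  k: 4
  s: 1000
  t_delay_ms: 5.0
  t_duration_ms: 200.0
  dt_ms: 0.025
  tau_syn_ms: 2.0
  stdp_on_random: false
stdp:
  tau_pre_ms: 10.0
  tau_post_ms: 10.0
  a_pre_us: 0.01
  a_post_us: -0.01
  w_max_us: 10.0
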