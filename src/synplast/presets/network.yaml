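# Reduced recurrent memory network (single-compartment excitatory cells).
# Population sizes and p_conn follow the reduced desk-scale paradigm; LIF
# constants, static weights, background drive and stimulus pulses are this
# package's documented defaults (the source model leaves them to its own
# configuration).
experiment: stc-network
seed: 1
trials: 10
network:
  n: 500
  n_exc: 400
  p_conn: 0.1
  v_rest_mv: -65.0
  v_reset_mv: -70.0
  v_thresh_mv: -55.0
  tau_m_ms: 10.0
  t_ref_ms: 2.0
  bg_mean_mv: 6.5
  bg_sigma_mv_sqrt_ms: 0.85
  w_ei_mv: 1.05
  w_ie_mv: -6.3
  w_ii_mv: -6.3
  delay_ms: 3.0
  weight_scale: 1.0
  syn_gain: 0.2
stimulus:
  n_assembly: 60
  t_learn_ms: 2000.0
  learn_dur_ms: 1000.0
  learn_rate_hz: 900.0
  learn_kick_mv: 2.0
  t_recall_ms: 13000.0
  recall_dur_ms: 500.0
  recall_rate_hz: 900.0
  recall_kick_mv: 2.0
  window_ms: 500.0
dt_ms: 0.5
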