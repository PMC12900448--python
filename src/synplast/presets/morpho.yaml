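# Morphological-cell variants for the consolidation network.  Each cell is
# a two-cylinder soma with a PRP-synthesis compartment at its middle plus
# apical and basal branches; c_morpho corrects the recurrent synaptic
# impact at the soma for the morphology.  The network/stimulus sections
# mirror the single-compartment preset.
experiment: morpho-network
seed: 1
trials: 4
cell_size: small      # small (r 6 um) or large (r 12 um)
dendrites: short      # short (12.5/5 um) or long (25/10 um)
morphology:
  dl_comp_um: 1.0
  l_prp_um: 1.0
  d_sps_m2_s: 1.0e-11
  d_p_m2_s: 1.0e-11
  c_morpho:
    small_short: 1.035
    small_long: 1.020
    large_short: 1.030
    large_long: 1.018
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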