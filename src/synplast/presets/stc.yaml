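# Two-phase (early/late) plasticity with synaptic tagging and capture.
# Calcium amplitudes are the slice-conditioned values; network runs
# multiply c_pre and c_post by the in-vivo correction factor 0.6.
experiment: stc-protocols
seed: 1
trials: 10
stc:
  h0_mv: 4.20075          # = 0.5 * gamma_p / (gamma_p + gamma_d) * 10 mV
  tc_delay_s: 0.0188
  c_pre: 1.0
  c_post: 0.2758
  in_vivo_factor: 0.6
  tau_c_s: 0.0488
  tau_h_s: 688.4
  tau_p_min: 60.0
  tau_z_min: 60.0
  gamma_p: 1645.6
  gamma_d: 313.1
  theta_p: 3.0
  theta_d: 1.2
  sigma_pl_mv: 2.90436
  p_max_umol_l: 10.0
  theta_pro_mv: 2.10037   # = 0.5 h0
  theta_tag_mv: 0.840149  # = 0.2 h0
  f_int_l_umol: 0.1
  r_comp_um: 1.0e-3
  l_cell_um: 2.0e-3
protocols: [STET, WTET, SLFS, WLFS]
post_rate_hz: 0.2
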