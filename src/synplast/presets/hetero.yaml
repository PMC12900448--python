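# Heterosynaptic calcium-diffusion plasticity: four spines on an 80-um
# dendrite, spines 1 and 3 stimulated by a regular 10-ms-interval train.
experiment: hetero
seed: 1
hetero:
  gamma_p_per_s: 90.0
  gamma_d_per_s: 0.01
  theta_p_umol_l: 0.11
  theta_d_umol_l: 0.05
  r_head_um: 1.0
  l_head_um: 1.0
  r_dendrite_um: 1.0
  l_dendrite_um: 80.0
  dl_comp_um: 1.0
  tau_ca_ms: 100.0
  tau_i_ms: 1.0
  ca_fraction: 0.11
  i0_pa: 0.75  # implementation-dependent amplitude (see docs/methods.md)
  diffusivity_m2_s: 2.2e-10
  w_init: 0.5
  stim_interval_ms: 10.0
run:
  t_stim_ms: 5000.0
  t_relax_ms: 1000.0
  dt_ms: 0.5
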