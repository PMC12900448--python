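# Spike-driven homeostasis: plastic fixed-rate input + static varying input.
# The 50 Hz fixed input rate is the regulated set point; LIF constants and
# the varying-rate schedule are this package's documented defaults (the
# source model leaves them to configuration).
experiment: homeostasis
seed: 1
trials: 50
homeostasis:
  w_init_na: 0.0
  w_max_na: 5.0
  dw_plus_na: 0.35
  dw_minus_na: -0.35
  w_varying_na: 3.5
  fixed_rate_hz: 50.0
  kick_mv_per_na: 8.0
  plastic: true
schedule:
  # (duration s, rate Hz); the zero-rate block is the silent period
  - [10.0, 20.0]
  - [10.0, 35.0]
  - [10.0, 50.0]
  - [10.0, 0.0]
  - [10.0, 40.0]
  - [10.0, 25.0]
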