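tier: analytic
seed: 7
thresholds:
  theta_m: 0.3
  theta_c: 0.8
  r_max: 2.0
feedback:
  dr: 0.4
  p_plus_a: 0.125
  p_minus_a: 0.375
  p_both: 0.5
  p_flip: 0.2
counts:
  n: 100000
  n_a: 60000
  n_b: 60000
  n_ab: 35000
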