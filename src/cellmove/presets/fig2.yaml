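# Directional bias only (alpha = 0) at high density in a 20 x 20 µm square.
# Interesting regimes: beta = 0.1 or 1 (regular patterns), -0.03 or -0.05
# (clustering). The weak repulsive case is the default; override model.beta.
model:
  m: 10.0
  alpha: 0.0
  sigma_w: 0.5
  beta: 0.1
  sigma_v: 0.5
  lambda_mu: 5.0
  sigma_mu: 0.05
  Lx: 20.0
  Ly: 20.0
  n: 200
numerics:
  delta: 0.1
  xi_max: 4.0
pcf:
  delta_r: 0.12
run:
  t_end: 25.0
  output_times: [25.0]
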