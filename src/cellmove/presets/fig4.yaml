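# Fibroblast-scale parameters: isolated-cell speed 50 µm/h decomposed into
# m = 5 h^-1 and mean step 10 µm; interaction range sigma_v = 10 µm (half the
# typical cell diameter); strip-shaped imaging geometry.
model:
  m: 5.0
  alpha: 0.0
  sigma_w: 10.0
  beta: 1000.0
  sigma_v: 10.0
  lambda_mu: 0.1
  sigma_mu: 2.5
  Lx: 4500.0
  Ly: 450.0
  n: 286
numerics:
  delta: 5.0
  xi_max: 150.0
pcf:
  delta_r: 8.0
run:
  t_end: 15.0
  output_times: [15.0]
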