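# Default experiment: 5-task class-incremental split on 100 Poisson inputs.
# Every key is optional; omitted keys keep the package defaults.
task:
  n_in: 100
  n_classes_total: 10
  n_tasks: 5
  T: 50
  rate_high: 0.5
  rate_low: 0.05
  active_frac: 0.2
  samples_per_class: 250
  test_samples_per_class: 50
  jitter: 0.02
  seed: 0
model:
  hidden: [100]
  kind: lif          # lif | alif
  recurrent: false
  variant: full      # full | no_gate | no_trace | no_homeostasis
neuron:
  tau_m: 20.0
  theta0: 1.0
  rho: 0.95
  beta: 0.0          # > 0 switches hidden layers to ALIF
surrogate:
  gamma: 0.3
  width: 1.0
astrocyte:
  tau_a: 2000.0
  eta_u: 0.1
  eta_s: 0.1
  eta_o: 1.0
  k_g: 1.0
  beta_g: 0.0
  stats_momentum: 0.99
  invert_gate: false
plasticity:
  eta: 0.05
  eta_decay: 0.0
  eta_b: 0.001
  r_target: 0.1
harness:
  max_train_samples_per_task: 200
  seeds: [0, 1, 2]
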