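# Canonical negative-monotonic (Sync-) parameterisation: strong
# depression of excitation, weak depression of inhibition.
neuron:
  amp_e: 3.7
  amp_i: 7.0
plasticity:
  mode: depression
  a_de: 0.4
  a_di: 0.1
  tau_pe: 0.15
  tau_pi: 0.10
stimulus:
  rates_hz: [8, 12, 16, 20, 24, 28, 32, 36, 40, 44, 48]
  duration_ms: 500
  pre_ms: 500
  post_ms: 500
experiment:
  n_trials: 10
  n_seeds: 1
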