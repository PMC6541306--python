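description: >
  Regime diagram of the non-adapting SOM-VIP motif with within-population
  recurrence: attenuation, amplification, between-population switch and
  the pathological winner-take-all states within populations.
circuit:
  variant: som_vip_only
  layout: {n_som: 5, n_vip: 5}
  # the pathological-state boundaries assume a fully connected motif
  probabilities: {"S<-V": 1.0, "V<-S": 1.0, "S<-S": 1.0, "V<-V": 1.0}
experiment:
  kind: bifurcation_grid
  params:
    w_values: [0.5, 1.5, 3.0, 6.0]
    recurrence_values: [0.0, 2.0, 5.0]
    amplification_threshold: 1.0
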