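description: >
  Regime diagram of the adapting SOM-VIP motif over mutual inhibition and
  adaptation strength: attenuation, amplification, winner-take-all switch
  and oscillation; empirical labels vs eigenvalue/closed-form boundaries.
circuit:
  variant: som_vip_only
  adaptation: {b: 0.2, tau_a: 0.05}
experiment:
  kind: bifurcation_grid
  params:
    w_values: [0.5, 0.9, 1.2, 1.5]
    b_values: [0.1, 0.5, 1.0, 1.5]
    tau_a: 0.05
    amplification_threshold: 1.0
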