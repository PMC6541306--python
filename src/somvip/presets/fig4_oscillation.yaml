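description: >
  Oscillation frequencies of the noiseless symmetric SOM-VIP motif across
  mutual inhibition, adaptation strength and adaptation time constant;
  Delta to Alpha band, compared against the linearized-theory frequency.
circuit:
  variant: som_vip_only
experiment:
  kind: oscillation_grid
  params:
    w_values: [1.3, 1.4]
    b_values: [0.5, 1.0]
    tau_a_values: [0.05, 0.1, 0.2]
    duration: 10.0
    discard: 2.0
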