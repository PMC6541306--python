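description: >
  Artificial recurrent inhibition within the SOM and VIP populations
  lowers the amplification index at fixed mutual inhibition.
circuit:
  variant: interneuron_only
  mutual_inhibition: 0.8
experiment:
  kind: recurrence_sweep
  params:
    w_r_values: [0.0, 0.25, 0.5]
    n_points: 17
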