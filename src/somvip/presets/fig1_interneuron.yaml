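description: >
  Amplification of modulatory input by the interneuron network (PV, SOM,
  VIP): steady-state response curves of the full network and of the
  reference network without VIP cells, and the amplification index.
circuit:
  variant: interneuron_only
  mutual_inhibition: 0.7
  adaptation: {b: 0.2, tau_a: 0.1}
  stf: {u_s: 0.4, tau_f: 0.2}
experiment:
  kind: amplification_curve
  params:
    n_points: 21
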