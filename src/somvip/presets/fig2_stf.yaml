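description: >
  Short-term facilitation of the mutual SOM<->VIP synapses raises the
  amplification index at fixed nominal mutual inhibition.
circuit:
  variant: interneuron_only
  mutual_inhibition: 0.7
experiment:
  kind: stf_sweep
  params:
    u_s_values: [1.0, 0.5, 0.25]
    tau_f: 0.1
    n_points: 17
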