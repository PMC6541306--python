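description: >
  Amplification in the full microcircuit with two-compartment pyramidal
  cells: PC-rate response curves under modulatory VIP input vs the
  reference circuit without VIP cells.
circuit:
  variant: full_circuit
  mutual_inhibition: 0.7
  adaptation: {b: 0.2, tau_a: 0.1}
  stf: {u_s: 0.4, tau_f: 0.2}
experiment:
  kind: amplification_curve
  params:
    x_lo: -3.0
    x_hi: 3.0
    n_points: 21
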