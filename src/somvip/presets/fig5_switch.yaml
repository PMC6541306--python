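description: >
  Integration vs cancellation of top-down input: the full microcircuit in
  a switch configuration transmits or suppresses the dendritic input
  stream depending on modulatory VIP input; bistability and hysteresis in
  the winner-take-all regime, with pulse-triggered persistent switching.
circuit:
  variant: full_circuit
  mutual_inhibition: 1.2
  totals: {"D<-S": 2.8}
  background: {E: 25.0, D: 7.0, P: 12.0, S: 3.5, V: 3.5}
experiment:
  kind: switch
  params:
    x_mod_levels: [-1.5, 1.5]
    omega_e: 5.0
    amp_e: 0.5
    omega_d: 30.0
    amp_d: 0.1
    pulse_amplitude: 8.4
    pulse_width: 0.01
    hysteresis: {x_lo: -1.0, x_hi: 1.0, n_steps: 11, w_values: [0.9, 1.1]}
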