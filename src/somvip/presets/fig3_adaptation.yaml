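description: >
  Frequency-resolved amplification: spike-frequency adaptation introduces
  a resonance whose frequency grows with adaptation strength, while the
  mutual inhibition strength sets the peak amplification.
circuit:
  variant: interneuron_only
  mutual_inhibition: 0.8
experiment:
  kind: frequency_response
  params:
    b_values: [0.0, 0.4, 0.8]
    tau_a: 0.1
    periods: [0.6, 0.4, 0.3, 0.2, 0.15, 0.1, 0.075, 0.05]
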