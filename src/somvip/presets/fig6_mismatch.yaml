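description: >
  Mismatch detection: visual input drives SOM, PV and the PC soma, a
  motor-related prediction drives VIP and the PC dendrite.  With tuned
  PV feedback the PCs respond only when the prediction arrives without
  the visual input, and more strongly in an amplification than in an
  attenuation configuration of the SOM-VIP motif.
circuit:
  variant: full_circuit
  mutual_inhibition: {sv: 0.9, vs: 1.1}
  background: {E: 28.0, D: 0.0}
experiment:
  kind: mismatch
  params:
    block_duration: 1.0
    amplitude: 10.5
    sd: 3.5
    attenuation_mutual: {sv: 0.1, vs: 0.3}
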