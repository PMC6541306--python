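description: >
  Population co-activity under shared plus individual input noise:
  recurrent inhibition decorrelates members of an interneuron class far
  more strongly than spike-frequency adaptation of matched strength.
circuit:
  variant: interneuron_only
  mutual_inhibition: 0.8
  layout: {size_multiplier: 5}
experiment:
  kind: correlations
  params:
    strength: 0.5
    duration: 4.0
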