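# Age-resolved branching-length laws, figure-caption labelling (8/10/12-day-old).
generator:
  branch_length_age_preset: figure
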