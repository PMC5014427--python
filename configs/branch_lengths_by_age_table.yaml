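# Age-resolved branching-length laws, tabulated labelling (5/7/9-day-old).
generator:
  branch_length_age_preset: table
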