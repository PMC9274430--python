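# Inclusion and exclusion criteria
inclusion criteria
exclusion criteria
eligibility criteria
were excluded if
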