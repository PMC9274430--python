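# Oligonucleotides (detected, never scored)
oligonucleotide
primer sequences
forward primer
reverse primer
siRNA targeting
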