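# Number of replications
in triplicate
in duplicate
in quadruplicate
three independent experiments
re:(?i)\bn\s*=\s*\d+\s+independent\b
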