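# General replication statements
were replicated
independently replicated
experiments were repeated
replicated independently
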