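# Protocol repository identifiers
re:protocols\.io/[A-Za-z0-9./_-]+
re:10\.17504/protocols\.io\.[a-z0-9]+
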