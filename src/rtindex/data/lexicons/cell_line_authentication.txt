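# Cell line authentication
authenticated by STR profiling
STR profiling
short tandem repeat profiling
cell line authentication
authenticated
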