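# Type of replication (biological vs technical)
biological replicates
technical replicates
biological replication
technical replication
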