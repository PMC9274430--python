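# Age reporting
weeks old
months old
years old
years of age
weeks of age
aged between
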