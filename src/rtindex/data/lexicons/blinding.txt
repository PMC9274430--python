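# Blinding of investigators or analysts
blinded
blinding
masked to group allocation
double-blind
single-blind
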