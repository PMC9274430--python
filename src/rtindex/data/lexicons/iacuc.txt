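# Institutional animal care and use committee statements
institutional animal care and use committee
IACUC
animal care committee
animal ethics committee
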