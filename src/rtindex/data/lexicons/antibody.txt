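# Antibodies
re:(?i)\banti-[\w-]+\s+antibod(?:y|ies)\b
primary antibody
secondary antibody
monoclonal antibody
polyclonal antibody
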