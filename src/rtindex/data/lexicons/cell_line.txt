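# Cell lines
HeLa cells
HEK293 cells
HEK293T cells
MCF-7 cells
U2OS cells
NIH/3T3 cells
CHO cells
Jurkat cells
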