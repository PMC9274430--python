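# Plasmids
pcDNA3.1
pGEX-4T-1
pLKO.1
psPAX2
pMD2.G
pEGFP-N1
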