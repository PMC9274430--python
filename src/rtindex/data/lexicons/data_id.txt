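# Data repository accession identifiers
re:\bGSE\d{3,}\b
re:\bGSM\d{3,}\b
re:\bSR[RXP]\d{5,}\b
re:\bPRJ(?:NA|EB|DB)\d+\b
re:\bE-MTAB-\d+\b
re:\bPXD\d{6}\b
re:\bERR\d{5,}\b
re:10\.5061/dryad\.\w+
re:10\.5281/zenodo\.\d+
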