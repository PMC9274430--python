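# Model organisms (strain-level cues)
C57BL/6J mice
BALB/c mice
Sprague-Dawley rats
Wistar rats
zebrafish
Drosophila melanogaster
Caenorhabditis elegans
transgenic mice
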