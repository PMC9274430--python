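# Attrition / drop-out statements
lost to follow-up
dropped out of the study
withdrew from the study
attrition
did not complete the study
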