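# Sex as a biological variable
male and female
female and male
both sexes
sex as a biological variable
of either sex
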