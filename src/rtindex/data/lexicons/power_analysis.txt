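# Power analysis for group size
power analysis
power calculation
sample size was calculated
sample size calculation
a priori power
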