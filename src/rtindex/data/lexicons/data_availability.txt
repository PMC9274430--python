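# Data availability statements
data is available upon request
data are available upon request
data available upon request
available in the supplementary
data availability statement
all data used within this study is available
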