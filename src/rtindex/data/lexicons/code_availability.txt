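# Code availability statements
code is available
code are available
code availability
scripts are available
source code is freely available
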