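# Institutional review board statements
institutional review board
IRB approval
IRB protocol
ethics committee approved
approved by the ethics committee
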