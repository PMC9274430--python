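# Informed consent statements
informed consent
written consent was obtained
consent was obtained from all
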