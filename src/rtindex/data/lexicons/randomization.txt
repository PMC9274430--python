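# Randomization of subjects into groups
randomly assigned
randomly allocated
randomized
randomised
random allocation
randomization
randomisation
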