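# Euthanasia statements and agents (merged type)
euthanized
euthanised
euthanasia
cervical dislocation
pentobarbital overdose
CO2 asphyxiation
isoflurane overdose
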