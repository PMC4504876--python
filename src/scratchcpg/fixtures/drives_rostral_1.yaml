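IP: 0.19
EP: 0.18
ER: 0.19
IR: 0.18
HE: 0.0
KE: 0.0
HF: 0.0
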