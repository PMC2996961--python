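BID
MYC
TNFRSF10A
TNFRSF10B
CASP8
DVL2
FBXO11
BAX
CASP3
TCF4
FADD
VPS16
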