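# schema: mhc.v1
peptide,mhc
W1,32
W2,16
W3,64
W4,128
W5,64
W6,32
W7,128
W8,128
W9,64
W10,32
W11,128
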