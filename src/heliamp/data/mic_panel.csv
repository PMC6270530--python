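# schema: mic.v1
strain,gram,W1,W2,W3,W4,W5,W6,W7,W8,W9,W10,W11
B. subtilis,positive,2,2,2,2,2,2,2,4,2,1,2
S. aureus,positive,2,2,2,2,2,2,2,2,2,1,2
S. epidermis,positive,2,2,4,2,2,2,2,4,2,1,2
M. luteus,positive,4,4,4,4,2,4,4,4,4,2,4
E. coli,negative,4,2,4,4,2,2,2,4,2,2,4
S. dysentariae,negative,2,1,2,2,2,2,2,4,2,1,2
S. typhimorium,negative,2,2,4,4,2,4,4,4,2,1,4
K. pneumoniae,negative,2,2,2,4,2,4,2,4,2,2,4
P. aeruginosa,negative,8,8,8,4,8,8,8,8,4,4,4
MRSA-TK784,other,8,8,8,16,8,4,16,16,8,4,16
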