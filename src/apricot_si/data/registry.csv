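allele1,allele2,group
S1,S2,I
S8,S9,II
S2,S6,III
S2,S7,IV
S2,S8,V
S6,S9,VIII
S7,S12,X
S9,S13,XI
S11,S13,XII
S6,S19,XIII
S7,S8,XV
S7,S11,XVI
S8,S12,XVII
S1,S3,XVIII
S2,S3,XIX
S2,S9,XX
S3,S8,XXI
S3,S9,XXII
S7,S9,XXIII
S1,S6,XXIV
S1,S9,XXV
S6,S8,XXVI
S1,S4,0
S12,S13,0
S1,S31,0
S20,S31,0
S1,S7,0
S3,S20,0
S10,S11,0
S7,S20,0
S2,S2,0
S2,S12,0
S2,S20,0
S5,S11,0
S5,S20,0
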