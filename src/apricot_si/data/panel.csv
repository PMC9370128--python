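assay,primer_f,primer_r,expected_bp,candidates,tolerance_bp,verified
SRC_FIRST_INTRON,CTCGCTTTCCTTGTTCTTGC,GGCCATTGTTGCACCCCTTG,358,S8|Sc,3,1
SRC_FIRST_INTRON,CTCGCTTTCCTTGTTCTTGC,GGCCATTGTTGCACCCCTTG,408,S1|S7,3,1
PRUC_SECOND_INTRON,CTTTGGCCAAGTAATTATTCAAACC,GGATGTGGTACGATTGAAGCG,1300,S6,3,0
PRUC_SECOND_INTRON,CTTTGGCCAAGTAATTATTCAAACC,GGATGTGGTACGATTGAAGCG,1500,S9,3,0
SHLM12,GGTGGAGGTGATAAGGTAGCC,GGCTGCATAAGGAAGCTGTAGG,650,S1,3,1
SHLM34,TATATCTTACTCTTTGGC,CACTATGATAATGTGTATG,413,S7,3,1
APRFBC8,CATGGAAAAAGCTGACTTATGG,GCCTCTAATGTCATCTACTCTTAG,150,S8,3,1
APRFBC8,CATGGAAAAAGCTGACTTATGG,GCCTCTAATGTCATCTACTCTTAG,500,Sc,3,1
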