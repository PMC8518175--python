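name	pattern
ABRE	ACGTG
G-box	CACGTG
ERE	AWTTCAAA
GT1-motif	GRWAAW
CGTCA-motif	CGTCA
TGACG-motif	TGACG
TCA-element	CCATCTTTTT
MBS	CAACTG
CAT-box	GCCACT
GARE-motif	TCTGTTG
TATC-box	TATCCCA
P-box	CCTTTTG
AuxRR-core	GGTCCAT
TGA-element	AACGAC
O2-site	GATGAYRTGR
CAMTA-core-CGCG	MCGCGB
CAMTA-core-CGTG	MCGTGT
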