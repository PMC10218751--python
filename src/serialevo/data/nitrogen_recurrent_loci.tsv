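locus	nitrogen_adaptive	missense	nonsense	indel	other_SNP	MHMI	MHMD	MHMGC	Ty_in_ORF	five_prime_Ty	three_prime_Ty	other_Ty_rearrangement	whole_gene_deletion
GAT1	yes	12	2	2	1	1	4	0	47	3	0	0	1
PAR32	yes	1	6	3	0	3	2	0	23	5	0	2	0
MEP1	yes	8	0	0	0	0	0	0	8	0	28	0	0
MEP2	yes	2	0	0	0	0	0	0	0	0	0	0	0
MEP3	yes	2	0	0	0	0	0	0	0	0	0	0	0
FCY2	yes	4	4	2	0	0	1	10	5	1	0	0	0
ARO80	no	3	0	0	0	0	0	0	1	0	0	0	0
TOR1	no	1	0	0	0	0	0	0	0	0	0	0	0
TOR2	no	0	1	0	0	0	0	0	0	0	0	0	0
GPB1	no	0	0	0	0	0	0	0	1	0	0	0	0
GPB2	no	2	0	0	0	0	0	0	0	0	0	0	0
SSK2	no	1	0	0	0	0	0	0	0	0	0	0	0
PDE1	no	1	0	0	0	0	0	0	0	0	0	0	0
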