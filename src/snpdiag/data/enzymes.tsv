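name	recognition	cut_top	cut_bottom
EcoRI	GAATTC	1	5
HindIII	AAGCTT	1	5
BamHI	GGATCC	1	5
XbaI	TCTAGA	1	5
EcoRV	GATATC	3	3
TaqI	TCGA	1	3
MseI	TTAA	1	3
AluI	AGCT	2	2
HaeIII	GGCC	2	2
RsaI	GTAC	2	2
DdeI	CTNAG	1	4
HinfI	GANTC	1	4
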