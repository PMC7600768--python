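gene	transcript	exon	cdna	protein	class	criteria	n_patients	familial	note	af_exomes_all	af_genomes_all	af_exomes_nfe	af_genomes_nfe	pred_sift	pred_polyphen	splice_ada	splice_rf	conservation	manual
TARDBP	NM_007375	6	c.881G>T	p.G294V	P	PM1, PM2, PM5, PP2, PP5(strong)	1	1	.	0	0	0	0	damaging	unknown	.	.	.	.
TARDBP	NM_007375	6	c.1127G>A	p.G376D	LP	PM1, PM2, PM5, PP2	1	1	.	0	0	0	0	damaging	unknown	.	.	.	.
TARDBP	NM_007375	6	c.1144G>A	p.A382T	P	PM1, PP2, PP5 (very strong)	6	1	.	2.4e-05	0	3.3e-05	0	damaging	unknown	.	.	.	.
OPTN	NM_021980	4	c.451C>T	p.Q151*	P	PVS1 (very strong), PM2, PP3	1	0	.	0	0	0	0	damaging	damaging	.	.	.	.
TBK1	NM_013254	6	c.684dupT	p.R229*	P	PVS1 (very strong), PM2, PP3	1	0	.	0	0	0	0	damaging	damaging	.	.	.	.
TBK1	NM_013254	13	c.1445_1446delAT	p.Y482*	P	PVS1 (very strong), PM2, PP3	1	0	.	0	0	0	0	damaging	damaging	.	.	.	.
TBK1	NM_013254	19	c.2040dupT	p.N681*	P	PVS1 (very strong), PM2, PP3	1	0	.	0	0	0	0	damaging	damaging	.	.	.	.
FUS	NM_004960	14	c.1540A>G	p.R514G	LP	PM1, PM2, PM5, PP2, PP3, PP5	1	1	.	0	0	0	0	damaging	damaging	.	.	.	.
SOD1	NM_000454	1	c.34G>T	p.D12Y	LP	PM1, PM2, PP2, PP3	3	1	.	0	0	0	0	damaging	damaging	.	.	.	.
SOD1	NM_000454	3	c.203T>C	p.L68P	LP	PM1, PM2, PM5, PP2, PP5	1	0	.	0	0	0	0	damaging	unknown	.	.	.	.
SOD1	NM_000454	3	c.217G>A	p.G73S	P	PS1, PM1, PM2, PP2, PP3, PP5 (strong)	1	0	.	0	0	0	0	damaging	damaging	.	.	.	.
SOD1	NM_000454	4	c.255G>C	p.L85F	P	PS1, PM1 (strong), PM2, PM5, PP2, PP3	1	1	.	0	0	0	0	damaging	damaging	.	.	.	PM1 (strong)
SOD1	NM_000454	4	c.256G>A	p.G86S	LP	PM1, PM2, PM5, PP2, PP3	1	0	.	0	0	0	0	damaging	damaging	.	.	.	.
SOD1	NM_000454	4	c.272A>C	p.D91A	LP	PM1, PM2, PM5, PP2, PP5	2	0	one patient homozygous, the other heterozygous	0	0	0	0	damaging	unknown	.	.	.	.
SOD1	NM_000454	4	c.281G>A	p.G94D	LP	PM1, PM2, PM5, PP2, PP3, PP5	1	0	.	0	0	0	0	damaging	damaging	.	.	.	.
SOD1	NM_000454	4	c.340A>T	p.I114F	LP	PM1, PM2, PM5, PP2, PP3, PP5	1	1	.	0	0	0	0	damaging	damaging	.	.	.	.
SOD1	NM_000454	5	c.435G>C	p.L145F	P	PS1, PM1 (strong), PM2, PM5, PP2, PP3, PP5 (strong)	2	1	.	0	0	0	0	damaging	damaging	.	.	.	PM1 (strong)
SOD1	NM_000454	5	c.449T>C	p.I150T	LP	PM1, PM2, PP2, PP3, PP5	1	1	.	0	0	0	0	damaging	damaging	.	.	.	.
NEK1	NM_001199397	29	c.2785_2786delGA	p.E929Nfs*12	P	PVS1 (very strong), PM2, PP3	1	0	.	0	0	0	0	damaging	damaging	.	.	.	.
VCP	NM_007126	5	c.463C>T	p.R155C	P	PM1 (strong), PM2, PM5, PP2, PP3, PP5 (very strong)	1	0	.	0	0	0	0	damaging	damaging	.	.	.	PM1 (strong)
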