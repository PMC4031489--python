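chrom	pos	ref	alt	gene	functional_class	cdna_change	protein_change	known_id	sift	polyphen_hvar	sanger_confirmed	maf_ESP6500
chr5	139936828	C	T	SRA1	nonsynonymous_SNV	c.C91T	p.P31S		0.00	1.00	true
chr16	30767746	C	T	PHKG2	nonsynonymous_SNV	c.C706T	p.R236W	rs143160739	0.00	1.00	true	0.0005
chr18	32919897	T	G	ZNF24	nonsynonymous_SNV	c.T464G	p.M155R		0.02	0.00	true
chr3	111797705	G	A	TMPRSS7	nonsynonymous_SNV	c.G1963A	p.G655S		0.00	1.00	true
chr4	8055946	G	A	ABLIM2	nonsynonymous_SNV	c.G791A	p.R264Q		0.05	1.00	true
chr3	71247489	C	T	FOXP1	nonsynonymous_SNV	c.C44T	p.A15V		0.34	0.98	true
chr7	142964824	G	A	GSTK1	nonsynonymous_SNV	c.G703A	p.G235R		0.02	1.00	true
chr12	55028594	C	T	LACRT	nonsynonymous_SNV	c.C32T	p.A11V		0.00	0.99	true
chr11	35456266	G	A	PAMR1	nonsynonymous_SNV	c.G1420A	p.G474R		0.00	1.00	true
chr2	179400887	G	A	TTN	stopgain	c.G73392A	p.W24464X		NA	NA	true
chr11	18553971	G	T	UEVLD	nonsynonymous_SNV	c.G1312T	p.V438L		0.37	0.96	true
chr5	52240783	C	G	ITGA1	nonsynonymous_SNV	c.C3296G	p.S1099C		0.01	1.00	true
chr17	65850386	A	C	BPTF	nonsynonymous_SNV	c.A944C	p.N315T		0.00	1.00	true
chr12	49220218	G	A	CACNB3	nonsynonymous_SNV	c.G688A	p.A230T		0.01	1.00	true
chrX	119680410	A	T	CUL4B	stopgain	c.A838T	p.R280X		NA	NA	true
chr7	80374250	G	A	SEMA3C	nonsynonymous_SNV	c.G2216A	p.R739Q		0.01	0.99	true
chr6	37280778	G	A	TBC1D22B	nonsynonymous_SNV	c.G1067A	p.S356N		0.03	0.39	true
chr10	75541868	G	T	CHCHD1	nonsynonymous_SNV	c.G35T	p.R12L		0.01	0.99	true
chr4	44177010	C	T	KCTD8	nonsynonymous_SNV	c.C1219T	p.R407C	rs370052455	0.00	1.00	true	0.0008
chrX	10176455	G	A	CLCN4	nonsynonymous_SNV	c.G1214A	p.C405Y		0.00	0.98	true
chr16	29000901	G	T	LAT	nonsynonymous_SNV	c.G634T	p.A212S		0.02	1.00	true
chr19	57868409	A	T	ZNF304	nonsynonymous_SNV	c.A1172T	p.Y391F		0.16	1.00	true
chrX	46359537	C	A	ZNF674	nonsynonymous_SNV	c.C1487A	p.P496H		0.00	1.00	true
chr1	1000000	A	G	GENED1	nonsynonymous_SNV	c.A10G	p.K4E		0.01	0.99	true
chr1	2000000	C	T	GENED2	nonsynonymous_SNV	c.C20T	p.A7V		0.01	0.99	true
chr2	3000000	G	A	GENED3	synonymous	c.G30A	p.L10L		0.50	0.10	true
chr3	4000000	T	C	GENED4	nonsynonymous_SNV	c.T40C	p.S14P	rs000001	0.01	0.99	true	0.05
chr4	50000000	A	C	GENED5	nonsynonymous_SNV	c.A50C	p.Q17P		0.50	0.20	true
chr5	6000000	G	T	GENED6	nonsynonymous_SNV	c.G60T	p.E20D		0.01	0.99	true
chr6	7000000	C	A	GENED7	nonsynonymous_SNV	c.C70A	p.P24T		0.01	0.99	false
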