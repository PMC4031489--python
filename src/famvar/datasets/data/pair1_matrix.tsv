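chrom	pos	ref	alt	gene	9	2	5	6
chr5	58147140	G	A	RAB3C	-	+	+	+
chr5	139936828	C	T	SRA1	-	+	+	+
chr3	111797705	G	A	TMPRSS7	-	+	+	+
chr18	32919897	T	G	ZNF24	-	+	+	+
chr12	55028594	C	T	LACRT	-	+	+	-
chr11	35456266	G	A	PAMR1	-	+	+	-
chr7	142964824	G	A	GSTK1	-	+	-	+
chr16	30767746	C	T	PHKG2	-	+	-	+
chr11	18553971	G	T	UEVLD	-	+	-	+
chr5	52240783	C	G	ITGA1	-	+	-	-
chr17	65850386	A	C	BPTF	-	-	+	-
chr6	37280778	G	A	TBC1D22B	-	-	+	-
chr7	80374250	G	A	SEMA3C	-	-	+	-
chrX	119680410	A	T	CUL4B	-	-	+	-
chrX	10176455	G	A	CLCN4	-	-	+	-
chr16	29000901	G	T	LAT	-	-	+	-
chr19	57868409	A	T	ZNF304	-	-	+	-
chrX	46359537	C	A	ZNF674	-	-	+	-
chr4	44177010	C	T	KCTD8	-	-	+	-
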