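chrom	pos	ref	alt	gene	1	2	4	3
chr16	30767746	C	T	PHKG2	+	+	+	-
chr7	142964824	G	A	GSTK1	+	+	-	-
chr5	52240783	C	G	ITGA1	+	+	-	-
chr11	35456266	G	A	PAMR1	+	+	-	-
chr3	111797705	G	A	TMPRSS7	+	+	-	-
chr11	18553971	G	T	UEVLD	+	+	-	-
chr12	55028594	C	T	LACRT	+	-	+	-
chr5	139936828	C	T	SRA1	+	-	+	-
chr18	32919897	T	G	ZNF24	+	-	+	-
chr4	8055946	G	A	ABLIM2	-	+	+	-
chr3	71247489	C	T	FOXP1	-	+	+	-
chr2	179400887	G	A	TTN	-	+	+	-
chr12	49220218	G	A	CACNB3	-	+	-	-
chr10	75541868	G	T	CHCHD1	-	+	-	-
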