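chrom	pos	ref	alt	gene	10	4	7	8
chr5	139936828	C	T	SRA1	-	+	+	+
chr16	30767746	C	T	PHKG2	-	+	+	-
chr1	160165804	G	A	CASQ1	-	+	+	-
chr4	8055946	G	A	ABLIM2	-	+	+	-
chr2	179400887	G	A	TTN	-	+	+	-
chr3	71247489	C	T	FOXP1	-	+	+	-
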