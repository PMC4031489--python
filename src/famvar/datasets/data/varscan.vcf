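##fileformat=VCFv4.2
##FILTER=<ID=PASS,Description="All filters passed">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##contig=<ID=chr1>
##contig=<ID=chr2>
##contig=<ID=chr3>
##contig=<ID=chr4>
##contig=<ID=chr5>
##contig=<ID=chr6>
##contig=<ID=chr7>
##contig=<ID=chr10>
##contig=<ID=chr11>
##contig=<ID=chr12>
##contig=<ID=chr16>
##contig=<ID=chr17>
##contig=<ID=chr18>
##contig=<ID=chr19>
##contig=<ID=chrX>
#CHROM	POS	ID	REF	ALT	QUAL	FILTER	INFO	FORMAT	1	2	3	4	5	6	7	8	9	10
chr1	2000000	.	C	T	.	.	.	GT	0/1	0/0	0/1	0/0	0/0	0/0	0/0	0/0	0/0	0/0
chr2	3000000	.	G	A	.	.	.	GT	0/0	0/1	0/0	0/0	0/0	0/0	0/0	0/0	0/0	0/0
chr2	179400887	.	G	A	.	.	.	GT	0/0	0/1	0/0	0/1	0/0	0/0	0/1	0/0	0/0	0/0
chr3	4000000	.	T	C	.	.	.	GT	0/0	0/0	0/0	0/1	0/0	0/0	0/0	0/0	0/0	0/0
chr3	71247489	.	C	T	.	.	.	GT	0/0	0/1	0/0	0/1	0/0	0/0	0/1	0/0	0/0	0/0
chr3	111797705	.	G	A	.	.	.	GT	0/1	0/1	0/0	0/0	0/1	0/1	0/0	0/0	0/0	0/0
chr4	8055946	.	G	A	.	.	.	GT	0/0	0/1	0/0	0/1	0/0	0/0	0/1	0/0	0/0	0/0
chr4	44177010	.	C	T	.	.	.	GT	0/0	0/0	0/0	0/0	0/1	0/0	0/0	0/0	0/0	0/0
chr4	50000000	.	A	C	.	.	.	GT	0/0	0/0	0/0	0/0	0/1	0/0	0/0	0/0	0/0	0/0
chr5	6000000	.	G	T	.	.	.	GT	0/0	0/0	0/0	0/0	0/1	0/0	0/0	0/0	0/1	0/0
chr5	52240783	.	C	G	.	.	.	GT	0/1	0/1	0/0	0/0	0/0	0/0	0/0	0/0	0/0	0/0
chr5	139936828	.	C	T	.	.	.	GT	0/1	0/1	0/0	0/1	0/1	0/1	0/1	0/1	0/0	0/0
chr6	7000000	.	C	A	.	.	.	GT	0/0	0/0	0/0	0/0	0/0	0/1	0/0	0/0	0/0	0/0
chr6	37280778	.	G	A	.	.	.	GT	0/0	0/0	0/0	0/0	0/1	0/0	0/0	0/0	0/0	0/0
chr7	80374250	.	G	A	.	.	.	GT	0/0	0/0	0/0	0/0	0/1	0/0	0/0	0/0	0/0	0/0
chr7	142964824	.	G	A	.	.	.	GT	0/1	0/1	0/0	0/0	0/0	0/1	0/0	0/0	0/0	0/0
chr10	75541868	.	G	T	.	.	.	GT	0/0	0/1	0/0	0/0	0/0	0/0	0/0	0/0	0/0	0/0
chr11	18553971	.	G	T	.	.	.	GT	0/0	0/1	0/0	0/0	0/0	0/1	0/0	0/0	0/0	0/0
chr11	35456266	.	G	A	.	.	.	GT	0/1	0/1	0/0	0/0	0/1	0/0	0/0	0/0	0/0	0/0
chr12	49220218	.	G	A	.	.	.	GT	0/0	0/1	0/0	0/0	0/0	0/0	0/0	0/0	0/0	0/0
chr12	55028594	.	C	T	.	.	.	GT	0/1	0/0	0/0	0/1	0/1	0/0	0/0	0/0	0/0	0/0
chr16	29000901	.	G	T	.	.	.	GT	0/0	0/0	0/0	0/0	0/1	0/0	0/0	0/0	0/0	0/0
chr16	30767746	.	C	T	.	.	.	GT	0/1	0/1	0/0	0/1	0/0	0/1	0/1	0/0	0/0	0/0
chr17	65850386	.	A	C	.	.	.	GT	0/0	0/0	0/0	0/0	0/1	0/0	0/0	0/0	0/0	0/0
chr18	32919897	.	T	G	.	.	.	GT	0/1	0/0	0/0	0/1	0/1	0/1	0/0	0/0	0/0	0/0
chr19	57868409	.	A	T	.	.	.	GT	0/0	0/0	0/0	0/0	0/1	0/0	0/0	0/0	0/0	0/0
chrX	10176455	.	G	A	.	.	.	GT	0/0	0/0	0/0	0/0	0/1	0/0	0/0	0/0	0/0	0/0
chrX	46359537	.	C	A	.	.	.	GT	0/0	0/0	0/0	0/0	0/1	0/0	0/0	0/0	0/0	0/0
chrX	119680410	.	A	T	.	.	.	GT	0/0	0/0	0/0	0/0	0/1	0/0	0/0	0/0	0/0	0/0
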