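FAM	1	0	0	2	2	1	62
FAM	2	0	0	2	2	1	53
FAM	3	0	0	2	1	0	65
FAM	4	0	0	2	2	1	35
FAM	9	0	0	1	1	0
FAM	10	0	0	1	1	0
FAM	5	9	2	2	2	1	35
FAM	6	9	2	2	2	1	36
FAM	7	10	4	2	2	1	35
FAM	8	10	4	1	1	0	45
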