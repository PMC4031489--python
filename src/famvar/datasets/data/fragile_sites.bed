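chr4	5149098	8732840	4A
chr11	31043423	36443424	11E
chr2	169791753	182991755	2G
chr11	16143423	21643424	11C
chr18	32746001	37246002	18A
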