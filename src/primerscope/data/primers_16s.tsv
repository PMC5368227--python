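name	sequence	orientation	ecoli_start	ecoli_end
68f	TNANACATGCAAGTCGRRCG	forward	49	68
518r	WTTACCGCGGCTGCTGG	reverse	518	534
341f	CCTACGGGNGGCWGCAG	forward	341	357
785r	GACTACHVGGGTATCTAATCC	reverse	785	805
799f	AACMGGATTAGATACCCKG	forward	781	799
1193r	ACGTCATCCCCACCTTCC	reverse	1177	1194
967f	CAACGCGAAGAACCTTACC	forward	967	985
1391r	GACGGGCGGTGWGTRCA	reverse	1391	1407
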