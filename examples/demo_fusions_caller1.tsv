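gene5	gene3	chrom5	pos5	chrom3	pos3	split_reads	spanning_pairs
PARTNER	GENE	chr7	2000100	chr7	3979900	6	3
DECOY1	DECOY2	chr7	550000	chr3	1050000	2	1
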