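gene5	gene3	chrom5	pos5	chrom3	pos3	split_reads	spanning_pairs
DECOY1	DECOY2	chr7	550020	chr3	1050010	4	2
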