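gene5	gene3	chrom5	pos5	chrom3	pos3	split_reads	spanning_pairs
DECOY2	DECOY1	chr3	1050005	chr7	550010	3	2
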