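chr7	1950000	2050000	PARTNER	0	-
chr7	3900000	4120000	GENE	0	-
chr7	500000	600000	DECOY1	0	+
chr3	1000000	1100000	DECOY2	0	-
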