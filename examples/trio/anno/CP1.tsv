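chrom	pos	ref	alt	gene	consequence	impact	dbsnp_af	esp_af	predictions
1	5000	A	G	TRIOE	missense_variant	MODERATE			D&D
2	100	A	G	TRIOI	intron_variant	MODIFIER			
2	200	C	T	TRIOJ	missense_variant	MODERATE	0.1	0.08	B
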