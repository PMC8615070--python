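chrom	pos	ref	alt	gene	consequence	impact	dbsnp_af	esp_af	predictions
2	300	G	C	TRIOK	synonymous_variant	LOW			
2	400	A	C	TRIOL	missense_variant	MODERATE	0.001		T&T&T
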