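chrom	pos	ref	alt	gene	consequence	impact	dbsnp_af	esp_af	predictions
1	1000	A	T	TRIOA	missense_variant	MODERATE			D&D&D
1	2000	G	A	TRIOB	synonymous_variant	LOW			
1	3000	C	T	TRIOC	missense_variant	MODERATE	0.02		D
1	4000	T	C	TRIOD	missense_variant	MODERATE			B&B&B
1	5000	A	G	TRIOE	missense_variant	MODERATE			D&D
1	6000	C	A	TRIOF	missense_variant	MODERATE			D&D
2	500	G	T	TRIOG	intron_variant	MODIFIER			
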