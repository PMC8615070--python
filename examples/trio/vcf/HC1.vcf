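##fileformat=VCFv4.2
##FILTER=<ID=PASS,Description="All filters passed">
##source=varsieve-simulator
##contig=<ID=1,length=20000000>
##contig=<ID=2,length=20000000>
##contig=<ID=3,length=20000000>
##contig=<ID=4,length=20000000>
##contig=<ID=5,length=20000000>
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
#CHROM	POS	ID	REF	ALT	QUAL	FILTER	INFO	FORMAT	HC1
2	300	.	G	C	.	.	.	GT	0/1
2	400	.	A	C	.	.	.	GT	0/1
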