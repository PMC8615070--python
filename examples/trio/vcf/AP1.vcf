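##fileformat=VCFv4.2
##FILTER=<ID=PASS,Description="All filters passed">
##source=varsieve-simulator
##contig=<ID=1,length=20000000>
##contig=<ID=2,length=20000000>
##contig=<ID=3,length=20000000>
##contig=<ID=4,length=20000000>
##contig=<ID=5,length=20000000>
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
#CHROM	POS	ID	REF	ALT	QUAL	FILTER	INFO	FORMAT	AP1
1	1000	.	A	T	.	.	.	GT	0/1
1	2000	.	G	A	.	.	.	GT	0/1
1	3000	.	C	T	.	.	.	GT	1/1
1	4000	.	T	C	.	.	.	GT	0/1
1	5000	.	A	G	.	.	.	GT	0/1
1	6000	.	C	A	.	.	.	GT	0/1
2	500	.	G	T	.	.	.	GT	1/1
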