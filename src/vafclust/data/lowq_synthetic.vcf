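##fileformat=VCFv4.2
##contig=<ID=chr_syn,length=10000>
##INFO=<ID=DP,Number=1,Type=Integer,Description="Total read depth">
##INFO=<ID=AO,Number=A,Type=Integer,Description="Alternate allele observation count">
#CHROM	POS	ID	REF	ALT	QUAL	FILTER	INFO
chr_syn	101	.	A	T	60	.	DP=20;AO=8
chr_syn	205	.	C	G	25	.	DP=30;AO=15
chr_syn	317	.	G	A	31.5	.	DP=25;AO=10
chr_syn	402	.	T	C	12	.	DP=18;AO=9
chr_syn	530	.	A	G	88.2	.	DP=40;AO=22
chr_syn	611	.	C	T	26	.	DP=15;AO=7
chr_syn	744	.	G	C	3.7	.	DP=22;AO=11
chr_syn	859	.	T	A	55	.	DP=33;AO=12
chr_syn	923	.	A	C	47.9	.	DP=28;AO=14
chr_syn	1001	.	C	A	99	.	DP=50;AO=25
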