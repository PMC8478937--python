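##fileformat=VCFv4.2
##INFO=<ID=AF,Number=A,Type=Float,Description="Allele Frequency">
##contig=<ID=1>
##contig=<ID=2>
#CHROM	POS	ID	REF	ALT	QUAL	FILTER	INFO
1	1500	rs101	G	A	.	.	AF=0.001
1	2500	rs102	C	T	.	.	AF=0.005
1	3500	.	A	G	.	.	AF=0.009
1	4500	rs104	C	G	.	.	AF=0.0871
1	5500	rs105	G	A	.	.	AF=0.0001
1	6500	rs106	C	T	.	.	AF=0.002
1	7500	rs107	T	C	.	.	AF=0.004
1	8500	.	G	T	.	.	AF=0.008
1	9500	rs109	A	C	.	.	AF=0.02
1	10500	rs110	C	T	.	.	AF=0.15
2	6000	rs201	G	A	.	.	AF=0.011
2	7000	rs202	C	T	.	.	AF=0.05
2	8000	rs203	T	A	.	.	AF=0.10
2	9000	rs204	A	T	.	.	AF=0.20
2	10000	rs205	G	C	.	.	AF=0.30
2	11000	rs206	C	A	.	.	AF=0.02
2	12000	rs207	G	T	.	.	AF=0.30
2	13000	rs208	A	G	.	.	AF=0.40
2	14000	rs209	T	C	.	.	AF=0.25
2	15000	rs210	C	T	.	.	AF=0.12
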