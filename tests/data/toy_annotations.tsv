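chrom	pos	ref	alt	gene	consequence	sift	polyphen2	provean	cadd_phred	vqsr
1	1500	G	A	GENEA	splice_acceptor				25.1	36
1	2500	C	T	GENEA	splice_donor				22.3
1	3500	A	G	GENEA	start_lost
1	4500	C	G	GENEA	stop_gained
1	5500	G	A	GENEA	missense	damaging	damaging	damaging
1	6500	C	T	GENEA	missense	damaging	damaging	tolerated
1	7500	T	C	GENEA	missense	damaging	tolerated
1	8500	G	T	GENEA	missense	damaging
1	9500	A	C	GENEA	missense	damaging	damaging
1	10500	C	T	GENEA	missense	0.01	0.9	-3.5
2	6000	G	A	GENEB	missense	tolerated	tolerated	tolerated
2	7000	C	T	GENEB	missense	damaging	tolerated	tolerated
2	8000	T	A	GENEB	missense	tolerated	tolerated
2	9000	A	T	GENEB	missense	tolerated
2	10000	G	C	GENEB	missense	0.5	0.1	0.0
2	11000	C	A	GENEB	intronic
2	12000	G	T	GENEB	intronic
2	13000	A	G	GENEB	upstream
2	14000	T	C	GENEB	downstream
2	15000	C	T	GENEB	utr
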