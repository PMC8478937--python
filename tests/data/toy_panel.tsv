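symbol	family	chrom	start	end
GENEA	ABC	1	1000	50999
GENEB	SLC	2	5000	25999
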