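gene	position	ref_allele	alt_allele	maf	rsid
ERAP2	1	G	T	0.45	rs2549782
ERAP2	2	A	G	0.55	rs2248374
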