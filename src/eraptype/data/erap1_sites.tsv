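gene	position	ref_residue	alt_residue	maf
ERAP1	56	E	K	0.09
ERAP1	127	P	R	0.44
ERAP1	276	I	M	0.22
ERAP1	346	G	D	0.10
ERAP1	349	M	V	0.10
ERAP1	528	K	R	0.60
ERAP1	575	D	N	0.11
ERAP1	725	R	Q	0.10
ERAP1	730	Q	E	0.68
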