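gene	codon	ref_aa	alt_aa	hrac_group	source
ACCase	1780	I	L	1	well-characterized cyclohexanedione/aryloxyphenoxypropionate resistance allele
ACCase	2078	D	G	1	published ACCase-inhibitor resistance substitution
ACCase	2096	G	A	1	published ACCase-inhibitor resistance substitution
ALS	197	P	*	2	any substitution at Pro197 confers ALS-inhibitor resistance in many species
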