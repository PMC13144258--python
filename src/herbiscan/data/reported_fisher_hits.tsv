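gene	herbicide	region	n_significant
ACCase7	fluazifop-butyl	intron	10
ACCase7	sethoxydim	exon	11
ACCase7	sethoxydim	intron	11
ALS	nicosulfuron	exon	3
GlutSynth9_2	glufosinate-ammonium	intron	1
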