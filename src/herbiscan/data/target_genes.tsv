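gene_id	acronym	name	chrom	start	end	strand
Seita.7G030200	ACCase7	Acetyl-CoA carboxylase	scaffold_7	8711297	8726543	reverse
Seita.9G271700	ACCase9	Acetyl-CoA carboxylase	scaffold_9	23428599	23440836	reverse
Seita.1G169700	ALS	Acetolactate synthase	scaffold_1	24269905	24272717	forward
Seita.4G023200	EPSP	5-enolpyruvylshikimate-3-phosphate synthase	scaffold_4	1557888	1561075	forward
Seita.1G311400	GlutSynth1	Glutamine synthetase	scaffold_1	37311880	37315284	reverse
Seita.3G024100	GlutSynth3	Glutamine synthetase	scaffold_3	1455306	1459782	reverse
Seita.9G118300	GlutSynth9_1	Glutamine synthetase	scaffold_9	7327714	7330961	forward
Seita.9G485600	GlutSynth9_2	Glutamine synthetase	scaffold_9	52568416	52571465	forward
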