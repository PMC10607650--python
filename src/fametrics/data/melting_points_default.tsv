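# canonical_label	melting_temp_C	source_note
C14:0	53.9	myristic acid; CRC Handbook of Chemistry and Physics
C16:0	62.9	palmitic acid; CRC Handbook of Chemistry and Physics
C16:1 cis 9	0.5	palmitoleic acid; lipid handbook value (literature -0.1 to 1)
C18:0	69.3	stearic acid; CRC Handbook of Chemistry and Physics
C18:1 cis 9	13.4	oleic acid; CRC Handbook of Chemistry and Physics
C18:1 cis 11	15.0	cis-vaccenic acid; approximate, literature 12-16
C18:2 cis 9, 12	-5.0	linoleic acid; lipid handbook value (literature -7 to -5)
C18:3 cis 9, 12, 15	-11.3	alpha-linolenic acid; lipid handbook value
C18:3 cis 6, 9, 12	-14.4	gamma-linolenic acid; lipid handbook value
C18:0 3OH	88.0	3-hydroxystearic acid; LOW CONFIDENCE, sparse literature
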