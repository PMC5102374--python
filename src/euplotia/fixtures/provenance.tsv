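taxon	dargyrome_type	FVC_count	habitat	ecozone
Euplotes_petzi	text	figure-transcription	figure-transcription	figure-transcription
Euplotes_sinicus	text	figure-transcription	figure-transcription	figure-transcription
Euplotes_vannus	text	figure-transcription	figure-transcription	figure-transcription
Euplotes_crassus	figure-transcription	figure-transcription	figure-transcription	figure-transcription
Euplotes_minuta	figure-transcription	figure-transcription	figure-transcription	figure-transcription
Euplotes_versatilis	figure-transcription	figure-transcription	figure-transcription	figure-transcription
Euplotes_muscicola	text	figure-transcription	text	figure-transcription
Euplotes_muscorum	text	figure-transcription	text	figure-transcription
Euplotes_antarcticus	table	table	text	figure-transcription
Euplotes_trisulcatus	table	table	figure-transcription	figure-transcription
Euplotes_balteatus	table	table	figure-transcription	figure-transcription
Euplotes_magnicirratus	table	table	figure-transcription	figure-transcription
Euplotes_parabalteatus	figure-transcription	figure-transcription	figure-transcription	figure-transcription
Euplotes_dammamensis	text	text	text	figure-transcription
Euplotes_euryhalinus	figure-transcription	figure-transcription	text	figure-transcription
Euplotes_aberrans	figure-transcription	figure-transcription	figure-transcription	figure-transcription
Euplotes_encysticus_1	figure-transcription	figure-transcription	figure-transcription	figure-transcription
Euplotes_encysticus_2	figure-transcription	figure-transcription	figure-transcription	figure-transcription
Euplotes_novemcarinatus	figure-transcription	figure-transcription	figure-transcription	figure-transcription
Euplotes_orientalis	figure-transcription	figure-transcription	figure-transcription	figure-transcription
Euplotes_shanghaiensis	figure-transcription	figure-transcription	figure-transcription	figure-transcription
Euplotes_cristatus	figure-transcription	figure-transcription	figure-transcription	figure-transcription
Euplotes_alatus	table	table	text	figure-transcription
Euplotes_platystoma	figure-transcription	figure-transcription	figure-transcription	figure-transcription
Euplotes_uncinatus	figure-transcription	figure-transcription	figure-transcription	figure-transcription
Euplotes_enigma	figure-transcription	figure-transcription	figure-transcription	figure-transcription
Euplotes_harpa	figure-transcription	figure-transcription	text	figure-transcription
Euplotes_neapolitanus	figure-transcription	figure-transcription	text	figure-transcription
Euplotes_eurystomus	text	figure-transcription	text	figure-transcription
Euplotes_octocarinatus	figure-transcription	figure-transcription	text	figure-transcription
Euplotes_plumipes	figure-transcription	figure-transcription	text	figure-transcription
Euplotes_patella	text	figure-transcription	text	figure-transcription
Euplotes_aediculatus	figure-transcription	figure-transcription	text	figure-transcription
Euplotes_amieti	figure-transcription	figure-transcription	figure-transcription	figure-transcription
Euplotes_daidaleos	figure-transcription	figure-transcription	figure-transcription	figure-transcription
Euplotes_woodruffi	figure-transcription	figure-transcription	text	figure-transcription
Euplotes_curdsi	text	text	text	text
Euplotes_nobilii	text	figure-transcription	text	figure-transcription
Euplotes_raikovi	text	figure-transcription	text	figure-transcription
Euplotes_qatarensis	text	text	text	figure-transcription
Euplotes_elegans	text	figure-transcription	text	figure-transcription
Euplotes_sp_FW	figure-transcription	figure-transcription	text	figure-transcription
Euplotes_focardii	figure-transcription	figure-transcription	figure-transcription	figure-transcription
Euplotes_quinquecarinatus	figure-transcription	figure-transcription	figure-transcription	figure-transcription
Euplotes_rariseta	figure-transcription	figure-transcription	figure-transcription	figure-transcription
Euplotes_parkei	figure-transcription	figure-transcription	figure-transcription	figure-transcription
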