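taxon	dargyrome_type	FVC_count	habitat	ecozone
Euplotes_petzi	double-patella	10	marine	polar
Euplotes_sinicus	double-patella	10	marine	temperate
Euplotes_vannus	single	10	marine	temperate
Euplotes_crassus	single	10	marine	temperate
Euplotes_minuta	single	9	marine	tropical
Euplotes_versatilis	multiple	10	freshwater	temperate
Euplotes_muscicola	multiple	10	freshwater	temperate
Euplotes_muscorum	complex	8	freshwater	temperate
Euplotes_antarcticus	?	10	marine	polar
Euplotes_trisulcatus	double-eurystomus	10	marine	temperate
Euplotes_balteatus	double-eurystomus	10	marine	temperate
Euplotes_magnicirratus	double-eurystomus	10	marine	temperate
Euplotes_parabalteatus	double-eurystomus	10	marine	?
Euplotes_dammamensis	?	10	hypersaline	tropical
Euplotes_euryhalinus	double-patella	10	marine|brackish	temperate
Euplotes_aberrans	double-eurystomus	9	marine	temperate
Euplotes_encysticus_1	double-eurystomus	10	freshwater	temperate
Euplotes_encysticus_2	double-eurystomus	10	freshwater	temperate
Euplotes_novemcarinatus	double-eurystomus	10	marine	temperate
Euplotes_orientalis	double-eurystomus	9	marine	temperate
Euplotes_shanghaiensis	double-eurystomus	10	marine	tropical
Euplotes_cristatus	double-eurystomus	10	marine	temperate
Euplotes_alatus	double-eurystomus	10	freshwater	temperate
Euplotes_platystoma	double-eurystomus	10	marine	temperate
Euplotes_uncinatus	double-eurystomus	10	marine	temperate
Euplotes_enigma	double-eurystomus	10	?	?
Euplotes_harpa	double-eurystomus	10	brackish	temperate
Euplotes_neapolitanus	double-eurystomus	10	marine	temperate
Euplotes_eurystomus	double-eurystomus	10	freshwater	temperate
Euplotes_octocarinatus	double-eurystomus	8	freshwater	temperate
Euplotes_plumipes	double-eurystomus	10	freshwater	temperate
Euplotes_patella	double-patella	10	freshwater	temperate
Euplotes_aediculatus	double-patella	10	freshwater	temperate
Euplotes_amieti	double-patella	10	freshwater	tropical
Euplotes_daidaleos	double-patella	10	freshwater	temperate
Euplotes_woodruffi	double-patella	10	freshwater|brackish	temperate
Euplotes_curdsi	double-eurystomus	10	brackish|marine	temperate|polar
Euplotes_nobilii	double-patella	10	marine	polar
Euplotes_raikovi	double-patella	10	marine	temperate
Euplotes_qatarensis	double-eurystomus	10	hypersaline	tropical
Euplotes_elegans	double-patella	10	marine	temperate
Euplotes_sp_FW	?	?	freshwater	temperate
Euplotes_focardii	double-eurystomus	10	marine	polar
Euplotes_quinquecarinatus	double-eurystomus	10	marine	temperate
Euplotes_rariseta	double-patella	7	marine	tropical
Euplotes_parkei	double-patella	9	marine	temperate
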