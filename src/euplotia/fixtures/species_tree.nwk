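((Euplotes_petzi:0.062,Euplotes_sinicus:0.058)100/1.00:0.031,(((Euplotes_vannus:0.021,(Euplotes_crassus:0.018,Euplotes_minuta:0.02)92/0.99:0.012)100/1.00:0.044,(Euplotes_versatilis:0.035,(Euplotes_muscicola:0.028,Euplotes_muscorum:0.031)96/1.00:0.016)100/1.00:0.041,(Euplotes_antarcticus:0.027,Euplotes_trisulcatus:0.03)99/1.00:0.037,((Euplotes_balteatus:0.022,Euplotes_magnicirratus:0.025)88/0.98:0.011,(Euplotes_parabalteatus:0.024,Euplotes_dammamensis:0.029)90/0.99:0.013)98/1.00:0.035,(Euplotes_euryhalinus:0.033,Euplotes_aberrans:0.03)97/1.00:0.036,((Euplotes_encysticus_1:0.006,Euplotes_encysticus_2:0.009)100/1.00:0.02,Euplotes_novemcarinatus:0.027)95/1.00:0.033,(Euplotes_orientalis:0.026,(Euplotes_shanghaiensis:0.021,Euplotes_cristatus:0.023)85/0.97:0.01)96/1.00:0.034,(Euplotes_alatus:0.028,(Euplotes_platystoma:0.024,(Euplotes_uncinatus:0.02,Euplotes_enigma:0.022)82/0.96:0.009)87/0.98:0.011)94/1.00:0.032)91/1.00:0.018,(((Euplotes_harpa:0.024,Euplotes_neapolitanus:0.026)98/1.00:0.022,((Euplotes_eurystomus:0.017,Euplotes_octocarinatus:0.02,Euplotes_plumipes:0.018)93/1.00:0.019,(Euplotes_patella:0.016,(Euplotes_aediculatus:0.014,(Euplotes_amieti:0.013,(Euplotes_daidaleos:0.015,Euplotes_woodruffi:0.018)89/0.99:0.007)90/0.99:0.008)95/1.00:0.01)100/1.00:0.021)97/1.00:0.012)100/1.00:0.02,((((Euplotes_curdsi:0.019,(Euplotes_nobilii:0.012,Euplotes_raikovi:0.014)99/1.00:0.009)96/1.00:0.011,Euplotes_qatarensis:0.027)92/1.00:0.01,(Euplotes_elegans:0.021,Euplotes_sp_FW:0.023)94/1.00:0.013)100/1.00:0.019,((Euplotes_focardii:0.023,Euplotes_quinquecarinatus:0.026)97/1.00:0.015,(Euplotes_rariseta:0.031,Euplotes_parkei:0.028)99/1.00:0.017)100/1.00:0.021)84/0.98:0.009)99/1.00:0.012):0.01);
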