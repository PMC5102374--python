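{
 "clades": {
  "A": ["Euplotes_vannus", "Euplotes_crassus", "Euplotes_minuta",
        "Euplotes_versatilis", "Euplotes_muscicola", "Euplotes_muscorum",
        "Euplotes_antarcticus", "Euplotes_trisulcatus",
        "Euplotes_balteatus", "Euplotes_magnicirratus",
        "Euplotes_parabalteatus", "Euplotes_dammamensis",
        "Euplotes_euryhalinus", "Euplotes_aberrans",
        "Euplotes_encysticus_1", "Euplotes_encysticus_2",
        "Euplotes_novemcarinatus", "Euplotes_orientalis",
        "Euplotes_shanghaiensis", "Euplotes_cristatus",
        "Euplotes_alatus", "Euplotes_platystoma",
        "Euplotes_uncinatus", "Euplotes_enigma"],
  "B": ["Euplotes_harpa", "Euplotes_neapolitanus",
        "Euplotes_eurystomus", "Euplotes_octocarinatus", "Euplotes_plumipes",
        "Euplotes_patella", "Euplotes_aediculatus", "Euplotes_amieti",
        "Euplotes_daidaleos", "Euplotes_woodruffi"],
  "C": ["Euplotes_curdsi", "Euplotes_nobilii", "Euplotes_raikovi",
        "Euplotes_qatarensis", "Euplotes_elegans", "Euplotes_sp_FW"],
  "D": ["Euplotes_focardii", "Euplotes_quinquecarinatus",
        "Euplotes_rariseta", "Euplotes_parkei"],
  "E": ["Euplotes_petzi", "Euplotes_sinicus"]
 },
 "subclades": {
  "petzi": ["Euplotes_petzi", "Euplotes_sinicus"],
  "vannus": ["Euplotes_vannus", "Euplotes_crassus", "Euplotes_minuta"],
  "muscicola": ["Euplotes_versatilis", "Euplotes_muscicola", "Euplotes_muscorum"],
  "antarcticus": ["Euplotes_antarcticus", "Euplotes_trisulcatus"],
  "balteatus": ["Euplotes_balteatus", "Euplotes_magnicirratus",
                "Euplotes_parabalteatus", "Euplotes_dammamensis"],
  "euryhalinus": ["Euplotes_euryhalinus", "Euplotes_aberrans"],
  "encysticus": ["Euplotes_encysticus_1", "Euplotes_encysticus_2",
                 "Euplotes_novemcarinatus"],
  "orientalis": ["Euplotes_orientalis", "Euplotes_shanghaiensis",
                 "Euplotes_cristatus"],
  "alatus": ["Euplotes_alatus", "Euplotes_platystoma",
             "Euplotes_uncinatus", "Euplotes_enigma"],
  "harpa": ["Euplotes_harpa", "Euplotes_neapolitanus"],
  "eurystomus": ["Euplotes_eurystomus", "Euplotes_octocarinatus",
                 "Euplotes_plumipes"],
  "patella": ["Euplotes_patella", "Euplotes_aediculatus", "Euplotes_amieti",
              "Euplotes_daidaleos", "Euplotes_woodruffi"],
  "curdsi": ["Euplotes_curdsi", "Euplotes_nobilii", "Euplotes_raikovi",
             "Euplotes_qatarensis", "Euplotes_elegans", "Euplotes_sp_FW"],
  "focardii": ["Euplotes_focardii", "Euplotes_quinquecarinatus"],
  "rariseta": ["Euplotes_rariseta", "Euplotes_parkei"]
 }
}
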