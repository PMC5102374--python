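{
 "notes": {
  "Euplotes_woodruffi": "Macronucleus conspicuously \"T\" shaped — the one strong exception to the usual \"C\"/\"3\" shape in the genus.",
  "Euplotes_dammamensis": "Dargyrome type unknown; hypersaline; >100 um, one of only two described 10-FVC species lacking a dargyrome report.",
  "Euplotes_antarcticus": "Dargyrome printed as double-eurystomus (?) in the comparative table; not discernible in the original description, encoded missing.",
  "Euplotes_curdsi": "Three populations: brackish lagoon (12 permille) and marine sites (32 and 25 permille); euryhaline, brackish and marine.",
  "Euplotes_sp_FW": "Undescribed freshwater population related to the marine E. elegans.",
  "Euplotes_charon": "Excluded from the fixture: represented by unrelated sequences, none with morphology; its phylogenetic position remains ambiguous (sequence AF492705 likely belongs to E. magnicirratus and was removed)."
 },
 "exclusions": ["Euplotes_charon", "AF492705"],
 "discrepancy_log": []
}
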