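{
 "schema_note": "Numeric traits: interval [min, max] or {approx: value} expanded to ±10% at load. Categorical traits: list of states. null = not reported / not discernible.",
 "profiles": [
  {
   "name": "Euplotes_curdsi",
   "provenance": "comparative table + diagnosis (this description)",
   "traits": {
    "size_length_um": [45, 65],
    "shape": ["oval", "ellipsoid", "rounded_posterior"],
    "peristome_extent_pct": {"approx": 70},
    "AZM_membranelles": [25, 34],
    "dorsal_ridges": ["inconspicuous"],
    "dargyrome_type": ["double-eurystomus"],
    "FVC_count": [10, 10],
    "dorsolateral_kineties": [6, 7],
    "middorsal_dikinetids": [10, 12]
   }
  },
  {
   "name": "Euplotes_antarcticus",
   "provenance": "comparative table (original description)",
   "traits": {
    "size_length_um": {"approx": 85},
    "shape": ["elongated", "pointed_posterior"],
    "peristome_extent_pct": {"approx": 75},
    "AZM_membranelles": {"approx": 30},
    "dorsal_ridges": ["prominent"],
    "dargyrome_type": null,
    "FVC_count": [10, 10],
    "dorsolateral_kineties": [8, 8],
    "middorsal_dikinetids": {"approx": 13}
   }
  },
  {
   "name": "Euplotes_magnicirratus",
   "provenance": "comparative table (original description)",
   "traits": {
    "size_length_um": [51, 65],
    "shape": ["oval"],
    "peristome_extent_pct": {"approx": 75},
    "AZM_membranelles": [49, 52],
    "dorsal_ridges": ["prominent"],
    "dargyrome_type": ["double-eurystomus"],
    "FVC_count": [10, 10],
    "dorsolateral_kineties": [8, 8],
    "middorsal_dikinetids": [13, 17]
   }
  },
  {
   "name": "Euplotes_alatus",
   "provenance": "comparative table (original description)",
   "traits": {
    "size_length_um": [36, 43],
    "shape": ["oval"],
    "peristome_extent_pct": {"approx": 50},
    "AZM_membranelles": {"approx": 26},
    "dorsal_ridges": ["inconspicuous"],
    "dargyrome_type": ["double-eurystomus"],
    "FVC_count": [10, 10],
    "dorsolateral_kineties": [8, 8],
    "middorsal_dikinetids": [10, 12]
   }
  },
  {
   "name": "Euplotes_trisulcatus",
   "provenance": "comparative table (original descriptions)",
   "traits": {
    "size_length_um": [35, 50],
    "shape": ["elongated", "pointed_posterior"],
    "peristome_extent_pct": {"approx": 65},
    "AZM_membranelles": [25, 36],
    "dorsal_ridges": ["prominent"],
    "dargyrome_type": ["double-eurystomus"],
    "FVC_count": [10, 10],
    "dorsolateral_kineties": [7, 7],
    "middorsal_dikinetids": {"approx": 11}
   }
  },
  {
   "name": "Euplotes_balteatus",
   "provenance": "comparative table (recent redescription)",
   "traits": {
    "size_length_um": [30, 150],
    "shape": ["oval"],
    "peristome_extent_pct": {"approx": 70},
    "AZM_membranelles": [25, 80],
    "dorsal_ridges": ["prominent"],
    "dargyrome_type": ["double-eurystomus"],
    "FVC_count": [10, 10],
    "dorsolateral_kineties": [7, 8],
    "middorsal_dikinetids": [10, 16]
   }
  }
 ]
}
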