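{
  "name": "GH16_trichoderma",
  "cleavable_linkages": [
    "L3",
    "L4"
  ],
  "required_linkage_minus2_minus1": "L3",
  "required_occupancy_minus2": true,
  "required_linkage_plus1_plus2": "L3",
  "plus2_may_be_empty": true,
  "min_substrate_dp": 4
}
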