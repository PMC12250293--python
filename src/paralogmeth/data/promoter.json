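{
 "name": "promoter",
 "primers": {
  "fwd": {"id": "promoter-F", "bases": "GAGGGGTTGGTTGGTTATTAG"},
  "rev": {"id": "promoter-R-btn", "bases": "TACCTACTCTCCCCCTCTC"},
  "seq": [{"id": "promoter-S", "bases": "GGTTGGTTGGTTATTAGA"}]
 },
 "dispensations": ["AGCTGGTCGTATCTAGTCGTAGTCAGTCTAGTCGTAGTCGAG"],
 "pair": null,
 "region": null,
 "windows": [],
 "include_shift_in_estimation": false,
 "max_mismatch": 3
}
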