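{
 "name": "exon2",
 "primers": {
  "fwd": {"id": "exon2-F", "bases": "GTTTTTTTTGGTAGGTTATGATGATGG"},
  "rev": {"id": "exon2-R-btn", "bases": "ACCCAACTCCTCAACCAAATCC"},
  "seq": [
   {"id": "exon2-S1", "bases": "AGGTTATGATGATGGGTA"},
   {"id": "exon2-S2", "bases": "GGGAGGGTTTTTTGGATA"}
  ]
 },
 "dispensations": [
  "AGCTAGTCAGACTGTAGCTGAGCTGTGTGTTGTACTAGCTAGCTGAGTATATGCTAGTACGTATTCGTATTGTATCGTATCGTGATGACTGTACTGTAGTCGAGTTGATGACTGTGTGTGTGTGATCAGTCGGCTAGCTGTGTACTGTAGCTAGCTGATGTGGTCGTAGTCGTG",
  "ACTGTGTGTGTGCTGTATCAGGTCGGCTAGCTGTGTACTGTAGCTAGCTGATGTGGTCGTAGTCGTG"
 ],
 "pair": null,
 "region": null,
 "windows": [],
 "include_shift_in_estimation": false,
 "max_mismatch": 3
}
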