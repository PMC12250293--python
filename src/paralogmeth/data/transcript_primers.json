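{
 "sets": [
  {"set": 1, "region": "exon1a-exon2 boundary", "fwd": "GGAGGCCGATCCAGGTCA",
   "rev": "CAGCACCACCAGCGTGTC", "expected_bp": [155]},
  {"set": 2, "region": "exon2-exon2+ boundary", "fwd": "GCGGAAGGTCCCTCAGAA",
   "rev": "CAGCCAGCTTGCGATAACCA", "expected_bp": [131]},
  {"set": 3, "region": "exon1a-exon3 boundary", "fwd": "GATCCAGACATCCCCGATTG",
   "rev": "CCTGTAGGACCTTCGGTGA", "expected_bp": [95]},
  {"set": 4, "region": "exon1a / exon2", "fwd": "CAACGCACCGAATAGTTACG",
   "rev": "CAGCACCACCAGCGTGTC", "expected_bp": [178, 452]},
  {"set": 5, "region": "exon1a / exon3", "fwd": "CAACGCACCGAATAGTTACG",
   "rev": "CAGTTGTGGCCCTGTAGGA", "expected_bp": [434, 631, 708, 127]},
  {"set": 6, "region": "exon1a / exon3", "fwd": "GGTCGGGTAGAGGAGGTG",
   "rev": "AGGACCTTCGGTGACTGATGA", "expected_bp": [466, 663, 740, 159]}
 ]
}
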