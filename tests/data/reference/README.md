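# Optional reference-validation data (user-supplied)

The accession-tier test (`test_accession_tier_reference_validation`) runs
only when real reference sequence is placed here; it is skipped otherwise.
Nothing is downloaded automatically.

Expected files:

* `grch38_regions.fa` — FASTA containing either GRCh38 chromosome 9
  (record id starting with `NC_000009.12`) or the two pre-extracted
  minus-strand regions named exactly
  `NC_000009.12:c21970915-21971191` (CDKN2A exon-2 CpG island) and
  `NC_000009.12:c22005889-22006230` (CDKN2B exon-2 CpG island),
  each with ~60 bp of flanking sequence if pre-extracted.
* `refseq_transcripts.fa` — optional; RefSeq cDNAs including
  `NM_000077.5` (p16INK4a) for the transcript-product check.

With these present, the test recomputes region identity (219/230 = 95%),
post-conversion identity, amplicon lengths (230 bp exon 2, 75 bp
promoter), GC contents (48.7% vs 47.8%), CpG counts (35), reverse-primer
mismatches on CDKN2B (1 unmethylated / 3 methylated) and the 95 bp
exon-boundary transcript product.
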