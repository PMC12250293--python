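"""Validation against user-supplied reference sequences.

The desk-pure test suite runs entirely on synthetic fixtures. This module
implements the optional validation tier that checks the published assay
characteristics on real GRCh38 chr9 sequence and RefSeq transcripts:
target-region identity, post-conversion identity, amplicon lengths, GC
contents, CpG counts and reverse-primer mispriming on CDKN2B. It never
downloads anything; the caller supplies FASTA files.

Expected inputs: a FASTA holding chromosome 9 (record id starting with
``NC_000009.12``) or pre-extracted regions, and optionally a transcript
FASTA holding ``NM_000077.5`` (p16INK4a cDNA).
"""

from __future__ import annotations

from .errors import ParalogMethError
from .io import builtin_config, read_fasta
from .sequences import (
    GenomicRegion,
    MethylationPattern,
    NucleotideSequence,
    bisulfite_convert,
    find_cpg_sites,
    gc_percent,
    match_primer,
    pairwise_identity,
    predict_amplicon,
)

#: CpG-island regions of the exon-2 assay (minus strand; the assay reads
#: the bisulfite-converted lower genomic strand).
REGION_CDKN2A = "NC_000009.12:c21970915-21971191"
REGION_CDKN2B = "NC_000009.12:c22005889-22006230"


def extract_region(sequences, region_text: str,
                   margin: int = 0) -> NucleotideSequence:
    """Cut a coordinate region out of user-supplied records.

    Accepts either a record whose id *is* the region string (pre-extracted,
    already minus-strand oriented when 'c'-prefixed) or a chromosome-scale
    record matching the accession, from which the slice is taken and
    reverse-complemented for minus-strand regions.
    """
    region = GenomicRegion.from_ncbi(region_text)
    for seq in sequences:
        if seq.id == region_text or seq.id.replace("–", "-") == region_text:
            return seq
    for seq in sequences:
        if seq.id.split()[0].startswith(region.chromosome):
            lo = region.start - 1 - margin
            hi = region.end + margin
            if hi > len(seq):
                raise ParalogMethError(
                    f"record {seq.id} too short for {region_text}"
                )
            sub = seq.subsequence(max(lo, 0), hi, id=region_text)
            return sub.reverse_complement(id=region_text) \
                if region.strand == "-" else sub
    raise ParalogMethError(
        f"no record matching {region.chromosome} found in the supplied FASTA"
    )


def validate_reference(genome_fasta, transcripts_fasta=None,
                       margin: int = 60) -> dict:
    """Recompute the published assay characteristics from real sequence.

    Returns a dict of measured quantities; every value is computed from the
    supplied FASTA at call time. ``margin`` extends the extracted regions so
    primer sites just outside the annotated CpG islands are included.
    """
    records = read_fasta(genome_fasta)
    region_a = extract_region(records, REGION_CDKN2A)
    region_b = extract_region(records, REGION_CDKN2B)
    wide_a = extract_region(records, REGION_CDKN2A, margin=margin)
    wide_b = extract_region(records, REGION_CDKN2B, margin=margin)

    out: dict = {
        "cpg_count_region_a": len(find_cpg_sites(region_a)),
        "cpg_count_region_b": len(find_cpg_sites(region_b)),
    }

    config = builtin_config("exon2")
    fwd, rev = config.primers.forward, config.primers.reverse
    meth = MethylationPattern.methylated()
    unmeth = MethylationPattern.unmethylated()

    products = {}
    for label, wide in (("a", wide_a), ("b", wide_b)):
        for state, pattern in (("methylated", meth), ("unmethylated", unmeth)):
            conv = bisulfite_convert(wide, pattern)
            hits = predict_amplicon(fwd, rev, conv, max_mismatch=3)
            if hits:
                products[(label, state)] = hits[0]
                out[f"amplicon_bp_{label}_{state}"] = hits[0].length
            rev_hits = match_primer(rev, conv, "-", max_mismatch=3)
            if rev_hits:
                out[f"reverse_primer_mismatches_{label}_{state}"] = \
                    rev_hits[0].mismatch_count

    # unconverted target-region identity over the amplicon span
    amp_a = products.get(("a", "unmethylated"))
    amp_b = products.get(("b", "unmethylated"))
    if amp_a and amp_b:
        raw_a = wide_a.subsequence(amp_a.forward_hit.offset,
                                   amp_a.forward_hit.offset + amp_a.length)
        raw_b = wide_b.subsequence(amp_b.forward_hit.offset,
                                   amp_b.forward_hit.offset + amp_b.length)
        ident = pairwise_identity(raw_a, raw_b)
        out["target_identity_percent"] = round(ident.percent, 1)
        out["target_identity_matches"] = ident.matches
        out["target_identity_length"] = ident.alignment_length
        for state, pattern in (("methylated", meth), ("unmethylated", unmeth)):
            ca = bisulfite_convert(raw_a, pattern)
            cb = bisulfite_convert(raw_b, pattern)
            out[f"converted_identity_percent_{state}"] = round(
                pairwise_identity(ca, cb).percent, 1)
            out[f"gc_percent_a_{state}"] = round(gc_percent(ca), 1)
            out[f"gc_percent_b_{state}"] = round(gc_percent(cb), 1)

    # promoter product length, searched on every supplied record
    prom = builtin_config("promoter")
    for rec in records:
        for oriented in (rec, rec.reverse_complement()):
            conv = bisulfite_convert(oriented, unmeth)
            hits = predict_amplicon(prom.primers.forward, prom.primers.reverse,
                                    conv, max_mismatch=0)
            if hits:
                out["promoter_amplicon_bp"] = hits[0].length
                break
        if "promoter_amplicon_bp" in out:
            break

    if transcripts_fasta is not None:
        out.update(validate_transcripts(transcripts_fasta))
    return out


def validate_transcripts(transcripts_fasta) -> dict:
    """Predict the exon-boundary RT-PCR product on the p16INK4a cDNA."""
    import json
    from importlib import resources

    records = {s.id.split()[0].split("|")[0]: s
               for s in read_fasta(transcripts_fasta)}
    out: dict = {}
    cdna = None
    for rid, seq in records.items():
        if rid.startswith("NM_000077"):
            cdna = seq
            break
    if cdna is None:
        return out
    sets = json.loads(resources.files("paralogmeth.data")
                      .joinpath("transcript_primers.json").read_text())["sets"]
    set3 = next(s for s in sets if s["set"] == 3)
    fwd = NucleotideSequence(id="set3-F", bases=set3["fwd"])
    rev = NucleotideSequence(id="set3-R", bases=set3["rev"])
    hits = predict_amplicon(fwd, rev, cdna, max_mismatch=0)
    if hits:
        out["transcript_set3_product_bp"] = hits[0].length
    return out
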