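"""Sequence-level primitives for bisulfite methylation assays.

This module holds everything that operates on plain nucleotide sequences:
CpG enumeration, in-silico bisulfite conversion, global pairwise identity,
GC content, primer matching with a mismatch budget, amplicon prediction on
genomic and spliced-transcript templates.

Conventions
-----------
* Genomic coordinates are 1-based inclusive (:class:`GenomicRegion`); NCBI
  ``c``-prefixed ranges denote the minus strand. Internal indices are
  0-based half-open.
* Assay sequences are held as the strand that is bisulfite-converted and
  sequenced (for the CDKN2A/CDKN2B exon-2 assay this is the lower genomic
  strand, written 5'->3').
* Bisulfite conversion turns every cytosine outside a CpG context into
  thymine; a CpG cytosine is retained only where the attached methylation
  pattern marks the site methylated.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from Bio import Align
from Bio.SeqUtils import gc_fraction as _bio_gc_fraction

from .errors import PatternError, SequenceError

_ALPHABET = frozenset("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: Modes a methylation pattern may take.
ALL_UNMETHYLATED = "all_unmethylated"
ALL_METHYLATED = "all_methylated"
PER_SITE = "per_site"


@dataclass(frozen=True)
class GenomicRegion:
    """A 1-based inclusive genomic interval on a named assembly.

    ``strand`` is ``'+'`` or ``'-'``; NCBI ``c``-prefixed coordinate ranges
    (complement) are stored as minus strand with ``start <= end``.
    """

    assembly: str
    chromosome: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.start < 1 or self.start > self.end:
            raise SequenceError(
                f"invalid region {self.start}-{self.end}: need 1 <= start <= end"
            )
        if self.strand not in ("+", "-"):
            raise SequenceError(f"strand must be '+' or '-', got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @classmethod
    def from_ncbi(cls, text: str, assembly: str = "GRCh38") -> "GenomicRegion":
        """Parse an NCBI range such as ``NC_000009.12:c21970915-21971191``.

        A ``c`` prefix on the coordinates means the feature lies on the
        minus strand; coordinates are normalized to ``start <= end``.
        """
        m = re.fullmatch(
            r"(?P<chrom>[^:]+):(?P<c>c?)(?P<a>\d+)[-–](?P<b>\d+)", text.strip()
        )
        if not m:
            raise SequenceError(f"cannot parse NCBI range {text!r}")
        a, b = int(m.group("a")), int(m.group("b"))
        start, end = min(a, b), max(a, b)
        strand = "-" if m.group("c") else "+"
        return cls(assembly=assembly, chromosome=m.group("chrom"),
                   start=start, end=end, strand=strand)


@dataclass(frozen=True, eq=True)
class NucleotideSequence:
    """An uppercase DNA sequence over ``{A, C, G, T, N}`` with a label.

    ``annotations`` is free-form provenance (e.g. exon boundaries recorded
    by :func:`splice_transcript`); it is excluded from equality.
    """

    id: str
    bases: str
    region: GenomicRegion | None = None
    annotations: Mapping[str, object] = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        bases = self.bases.upper()
        if not bases:
            raise SequenceError(f"sequence {self.id!r} is empty")
        bad = set(bases) - _ALPHABET
        if bad:
            raise SequenceError(
                f"sequence {self.id!r} contains characters outside ACGTN: {sorted(bad)}"
            )
        object.__setattr__(self, "bases", bases)

    def __len__(self) -> int:
        return len(self.bases)

    def __str__(self) -> str:
        return self.bases

    def reverse_complement(self, id: str | None = None) -> "NucleotideSequence":
        return NucleotideSequence(
            id=id or f"{self.id}|rc",
            bases=self.bases.translate(_COMPLEMENT)[::-1],
        )

    def subsequence(self, start: int, end: int, id: str | None = None) -> "NucleotideSequence":
        """0-based half-open slice as a new sequence."""
        return NucleotideSequence(id=id or f"{self.id}[{start}:{end}]",
                                  bases=self.bases[start:end])


@dataclass(frozen=True)
class MethylationPattern:
    """Methylation state of the CpG sites of one sequence.

    ``site_states`` maps the 0-based sequence index of a CpG cytosine to a
    boolean (or 0/1) methylation flag. Fractional states in (0, 1) are legal
    to carry around (they describe ensemble averages) but cannot be applied
    by :func:`bisulfite_convert`, which operates on single molecules.
    """

    mode: str = ALL_UNMETHYLATED
    site_states: Mapping[int, float] | None = None

    def __post_init__(self) -> None:
        if self.mode not in (ALL_UNMETHYLATED, ALL_METHYLATED, PER_SITE):
            raise PatternError(f"unknown methylation pattern mode {self.mode!r}")
        if self.mode == PER_SITE and self.site_states is None:
            raise PatternError("per_site pattern requires site_states")
        if self.site_states:
            for idx, state in self.site_states.items():
                if not 0.0 <= float(state) <= 1.0:
                    raise PatternError(
                        f"site state at index {idx} outside [0, 1]: {state}"
                    )

    @classmethod
    def unmethylated(cls) -> "MethylationPattern":
        return cls(ALL_UNMETHYLATED)

    @classmethod
    def methylated(cls) -> "MethylationPattern":
        return cls(ALL_METHYLATED)

    @classmethod
    def per_site(cls, states: Mapping[int, float]) -> "MethylationPattern":
        return cls(PER_SITE, dict(states))


@dataclass(frozen=True)
class IdentityResult:
    """Outcome of a global pairwise alignment, as matches over columns."""

    matches: int
    alignment_length: int

    def __post_init__(self) -> None:
        if not 0 <= self.matches <= self.alignment_length:
            raise SequenceError("matches must lie in [0, alignment_length]")

    @property
    def percent(self) -> float:
        return 100.0 * self.matches / self.alignment_length


@dataclass(frozen=True)
class AmpliconHit:
    """One primer binding site on a template.

    ``offset`` is the 0-based start of the matched span on the template (for
    reverse primers the span of the reverse-complemented primer).
    ``mismatch_offsets`` are 0-based positions *within the primer* (5'->3'
    in primer orientation).
    """

    primer_id: str
    template_id: str
    offset: int
    strand: str
    mismatch_count: int
    mismatch_offsets: tuple[int, ...]

    def __post_init__(self) -> None:
        if self.mismatch_count != len(self.mismatch_offsets):
            raise SequenceError("mismatch_count must equal len(mismatch_offsets)")


@dataclass(frozen=True)
class Amplicon:
    """A predicted PCR product: span from the forward primer 5' end to the
    5' end of the reverse primer site on the opposite strand, both primers
    included."""

    sequence: NucleotideSequence
    length: int
    forward_hit: AmpliconHit
    reverse_hit: AmpliconHit


def find_cpg_sites(seq: NucleotideSequence) -> list[int]:
    """Return the strictly increasing 0-based indices of CpG cytosines."""
    bases = seq.bases
    return [i for i in range(len(bases) - 1) if bases[i] == "C" and bases[i + 1] == "G"]


def bisulfite_convert(seq: NucleotideSequence,
                      pattern: MethylationPattern | None = None) -> NucleotideSequence:
    """In-silico bisulfite conversion of a single-molecule sequence.

    Every cytosine outside a CpG dinucleotide becomes thymine. A CpG
    cytosine is retained as C only where ``pattern`` marks it methylated.
    Length is always preserved (substitution-only model; no modeling of
    incomplete conversion here).
    """
    if pattern is None:
        pattern = MethylationPattern.unmethylated()
    cpg = set(find_cpg_sites(seq))
    states: dict[int, bool] = {}
    if pattern.mode == ALL_METHYLATED:
        states = {i: True for i in cpg}
    elif pattern.mode == PER_SITE:
        assert pattern.site_states is not None
        for idx, state in pattern.site_states.items():
            if idx not in cpg:
                raise PatternError(
                    f"pattern refers to index {idx}, which is not a CpG cytosine "
                    f"of sequence {seq.id!r}"
                )
            s = float(state)
            if s not in (0.0, 1.0):
                raise PatternError(
                    f"fractional methylation state {s} at index {idx} cannot be "
                    "applied to a single molecule; expand it into a template "
                    "ensemble instead"
                )
            states[idx] = bool(s)
    out = []
    for i, b in enumerate(seq.bases):
        if b == "C":
            out.append("C" if states.get(i, False) else "T")
        else:
            out.append(b)
    tag = {ALL_UNMETHYLATED: "u", ALL_METHYLATED: "m", PER_SITE: "p"}[pattern.mode]
    return NucleotideSequence(id=f"{seq.id}|bis:{tag}", bases="".join(out),
                              region=seq.region)


def pairwise_identity(a: NucleotideSequence, b: NucleotideSequence,
                      match: float = 1.0, mismatch: float = -1.0,
                      open_gap: float = -2.0, extend_gap: float = -0.5) -> IdentityResult:
    """Percent identity from a global (end-gap penalized) alignment.

    Identity is counted as matched columns over all alignment columns
    (matches + mismatches + gap columns), which reproduces the fixed-length
    convention used for homologous amplicon regions.
    """
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = open_gap
    aligner.extend_gap_score = extend_gap
    aln = aligner.align(a.bases, b.bases)[0]
    counts = aln.counts()
    length = counts.identities + counts.mismatches + counts.gaps
    return IdentityResult(matches=counts.identities, alignment_length=length)


def gc_percent(seq: NucleotideSequence) -> float:
    """GC content in percent (G + C over sequence length)."""
    return 100.0 * _bio_gc_fraction(seq.bases, ambiguous="ignore")


def _bases_match(p: str, t: str) -> bool:
    # N mismatches everything except N.
    return p == t


def match_primer(primer: NucleotideSequence, template: NucleotideSequence,
                 strand: str = "+", max_mismatch: int = 3) -> list[AmpliconHit]:
    """Hamming-scan a primer along a template, allowing ``max_mismatch``.

    Reverse primers (``strand='-'``) are reverse-complemented before the
    scan, so the reported ``offset`` is the start of the primer's binding
    span on the given template strand. Hits are sorted by mismatch count,
    then offset. Indels are not modeled.
    """
    if strand not in ("+", "-"):
        raise SequenceError(f"strand must be '+' or '-', got {strand!r}")
    if len(primer) >= len(template):
        raise SequenceError("primer must be shorter than template")
    probe = primer.bases if strand == "+" else primer.reverse_complement().bases
    n = len(probe)
    hits: list[AmpliconHit] = []
    tb = template.bases
    for off in range(len(tb) - n + 1):
        mis = [k for k in range(n) if not _bases_match(probe[k], tb[off + k])]
        if len(mis) <= max_mismatch:
            if strand == "-":
                primer_offsets = tuple(sorted(n - 1 - k for k in mis))
            else:
                primer_offsets = tuple(mis)
            hits.append(AmpliconHit(
                primer_id=primer.id, template_id=template.id, offset=off,
                strand=strand, mismatch_count=len(mis),
                mismatch_offsets=primer_offsets,
            ))
    hits.sort(key=lambda h: (h.mismatch_count, h.offset))
    return hits


def predict_amplicon(fwd: NucleotideSequence, rev: NucleotideSequence,
                     template: NucleotideSequence,
                     max_mismatch: int = 3) -> list[Amplicon]:
    """Enumerate predicted PCR products for a primer pair on a template.

    A product requires a forward site strictly upstream of the reverse
    site's far end and no overlap of the two primer spans. Returns an empty
    list when no product forms; every compatible site pair is enumerated.
    """
    fwd_hits = match_primer(fwd, template, "+", max_mismatch)
    rev_hits = match_primer(rev, template, "-", max_mismatch)
    products: list[Amplicon] = []
    for fh in fwd_hits:
        for rh in rev_hits:
            start = fh.offset
            end = rh.offset + len(rev)
            if end - start >= len(fwd) + len(rev):
                products.append(Amplicon(
                    sequence=template.subsequence(start, end,
                                                  id=f"{template.id}|amplicon"),
                    length=end - start,
                    forward_hit=fh, reverse_hit=rh,
                ))
    products.sort(key=lambda p: (p.forward_hit.offset, p.length))
    return products


def splice_transcript(exons: Sequence[NucleotideSequence],
                      id: str | None = None) -> NucleotideSequence:
    """Concatenate exons in order into a cDNA sequence.

    Exon boundaries are recorded in ``annotations['exon_boundaries']`` as
    cumulative 0-based offsets (including 0 and the total length), so a
    transcript lacking an internal exon is shorter by exactly that exon's
    length.
    """
    if not exons:
        raise SequenceError("at least one exon is required")
    bases = "".join(e.bases for e in exons)
    bounds = [0]
    for e in exons:
        bounds.append(bounds[-1] + len(e))
    return NucleotideSequence(
        id=id or "+".join(e.id for e in exons),
        bases=bases,
        annotations={"exon_boundaries": tuple(bounds),
                     "exon_ids": tuple(e.id for e in exons)},
    )
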