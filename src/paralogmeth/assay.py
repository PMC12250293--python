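"""Assay configuration and the pyrogram-position translation.

A duplex methylation assay co-amplifies two homologous paralogs (e.g.
CDKN2A exon 2 with CDKN2B exon 2) and sequences the mixed product. This
module knows which pyrogram positions carry CpG methylation signal, which
carry paralog-discriminating bases (used to estimate the proportion of each
co-amplified gene), and how the dispensation order maps template columns to
pyrogram peaks.

The central operation is :func:`map_dispensation_positions`: it sequences
each pure template (paralog x {all-methylated, all-unmethylated}) in silico
under the assay's dispensation order and derives, deterministically, the
variable-position map that the quantification modules consume.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .errors import AssayConfigError, StallError
from .pyrogram import DispensationOrder, template_walk
from .sequences import (
    MethylationPattern,
    NucleotideSequence,
    bisulfite_convert,
    find_cpg_sites,
    match_primer,
)

# classification labels for discriminating columns
A_SPECIFIC = "a_specific_base"
B_SPECIFIC = "b_specific_base"
CPG_SHIFT = "cpg_shift"


@dataclass(frozen=True)
class ParalogPair:
    """Two homologous sequences spanning the same assay window."""

    paralog_a: NucleotideSequence
    paralog_b: NucleotideSequence
    label_a: str = ""
    label_b: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "label_a", self.label_a or self.paralog_a.id)
        object.__setattr__(self, "label_b", self.label_b or self.paralog_b.id)
        if self.label_a == self.label_b:
            raise AssayConfigError("paralog labels must be distinct")


@dataclass(frozen=True)
class DiscriminatingSite:
    """A post-conversion alignment column at which the paralogs differ."""

    offset: int
    base_a: str
    base_b: str
    classification: str


@dataclass(frozen=True)
class VariablePosition:
    """One position-to-analyze in a pyrogram.

    ``pyrogram_index`` is the 1-based ordinal over positions-to-analyze in
    dispensation order within its sequencing primer's pyrogram ("pos N").
    ``dispensation_indices`` maps ``variant``/``reference`` to dispensation
    slot tuples: for a CpG, variant = C slots (methylated, retained
    cytosine) and reference = T slots; for a paralog marker, variant = the
    slots of the marked paralog's base.
    """

    pyrogram_index: int
    kind: str  # cpg | paralog_marker | cpg_shift
    dispensation_indices: Mapping[str, tuple[int, ...]]
    primer: int = 1
    marker_for: str | None = None
    cpg_number_a: int | None = None
    cpg_number_b: int | None = None
    specificity: str | None = None  # shared | a_specific | b_specific | None
    column: int | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("cpg", "paralog_marker", "cpg_shift"):
            raise AssayConfigError(f"unknown position kind {self.kind!r}")
        if self.kind == "paralog_marker" and self.marker_for is None:
            raise AssayConfigError("paralog_marker position requires marker_for")
        if self.kind == "cpg" and self.cpg_number_a is None and self.cpg_number_b is None:
            raise AssayConfigError("cpg position requires at least one CpG number")


@dataclass(frozen=True)
class Primers:
    forward: NucleotideSequence | None
    reverse: NucleotideSequence | None
    sequencing: tuple[NucleotideSequence, ...] = ()


@dataclass(frozen=True)
class AssayConfig:
    """A complete assay definition.

    ``windows`` gives, per sequencing primer, the 0-based half-open read
    window on the assay sequence (the stretch synthesized downstream of that
    primer's 3' end). ``pair`` is set for duplex paralog assays; single-locus
    assays (e.g. a promoter) set ``region`` instead.
    """

    name: str
    primers: Primers
    dispensations: tuple[DispensationOrder, ...] = ()
    pair: ParalogPair | None = None
    region: NucleotideSequence | None = None
    windows: tuple[tuple[int, int], ...] = ()
    include_shift_in_estimation: bool = False
    max_mismatch: int = 3

    def __post_init__(self) -> None:
        if not self.name:
            raise AssayConfigError("assay needs a name")
        if self.pair is not None and self.region is not None:
            raise AssayConfigError("set either pair or region, not both")
        if self.windows and len(self.windows) != len(self.dispensations):
            raise AssayConfigError("one dispensation order per sequencing window")
        for w0, w1 in self.windows:
            if not 0 <= w0 < w1:
                raise AssayConfigError(f"invalid window ({w0}, {w1})")

    @property
    def assay_sequences(self) -> dict[str, NucleotideSequence]:
        """Label -> template sequence for every locus in the assay."""
        if self.pair is not None:
            return {self.pair.label_a: self.pair.paralog_a,
                    self.pair.label_b: self.pair.paralog_b}
        if self.region is not None:
            return {self.region.id: self.region}
        return {}


def discover_discriminating_positions(
    pair: ParalogPair,
    pattern_a: MethylationPattern,
    pattern_b: MethylationPattern,
    window: tuple[int, int] | None = None,
) -> list[DiscriminatingSite]:
    """Columns at which the two converted paralogs differ, classified.

    The paralogs must be column-aligned (equal length; the assay model is
    substitution-only). Classification: a column inside CpGs of both
    paralogs whose start offsets differ is a ``cpg_shift``; a column where
    exactly one paralog has a CpG cytosine is specific for that paralog;
    otherwise the column is attributed to the paralog carrying an adenine
    (the discriminating transversion base), falling back to the purine
    carrier.
    """
    if len(pair.paralog_a) != len(pair.paralog_b):
        raise AssayConfigError(
            "paralogs must be column-aligned (equal length) for discovery"
        )
    n = len(pair.paralog_a)
    if window is None:
        window = (0, n)
    w0, w1 = window
    if not (0 <= w0 < w1 <= n):
        raise AssayConfigError(f"window ({w0}, {w1}) outside sequences of length {n}")

    conv_a = bisulfite_convert(pair.paralog_a, pattern_a).bases
    conv_b = bisulfite_convert(pair.paralog_b, pattern_b).bases
    sites_a = set(find_cpg_sites(pair.paralog_a))
    sites_b = set(find_cpg_sites(pair.paralog_b))
    shift_cols = _shift_columns(sites_a, sites_b)

    out: list[DiscriminatingSite] = []
    for j in range(w0, w1):
        ba, bb = conv_a[j], conv_b[j]
        if ba == bb:
            continue
        if j in shift_cols:
            cls = CPG_SHIFT
        elif j in sites_a and j not in sites_b:
            cls = A_SPECIFIC
        elif j in sites_b and j not in sites_a:
            cls = B_SPECIFIC
        elif ba == "A" and bb != "A":
            cls = A_SPECIFIC
        elif bb == "A":
            cls = B_SPECIFIC
        else:
            cls = A_SPECIFIC if ba in "AG" else B_SPECIFIC
        out.append(DiscriminatingSite(offset=j, base_a=ba, base_b=bb,
                                      classification=cls))
    return out


def _shift_columns(sites_a: set[int], sites_b: set[int]) -> set[int]:
    """Columns belonging to CpGs whose start position differs by one base
    between the paralogs (the 'shifted CpG' geometry)."""
    cols: set[int] = set()
    for s in sites_a:
        if s not in sites_b:
            for d in (-1, 1):
                if s + d in sites_b and s + d not in sites_a:
                    cols.update({s, s + 1, s + d, s + d + 1})
    return cols


def design_dispensation(reads: Sequence[str]) -> str:
    """Derive a dispensation order that keeps an ensemble of column-aligned
    reads synchronized and fully consumed.

    Greedy rule: repeatedly look at the templates whose pointer is furthest
    behind, collect the bases they need next, and dispense the first in
    A<C<G<T order. Each dispensation advances every template by its
    homopolymer run of the dispensed base. The most-behind template advances
    within at most four dispensations, so the walk terminates.
    """
    reads = [r for r in reads if r]
    if not reads:
        raise AssayConfigError("no reads to design a dispensation for")
    pointers = [0] * len(reads)
    disp: list[str] = []
    guard = 8 * max(len(r) for r in reads) + 16
    while True:
        active = [i for i, r in enumerate(reads) if pointers[i] < len(r)]
        if not active:
            break
        if len(disp) > guard:  # pragma: no cover - safety net
            raise AssayConfigError("dispensation design failed to terminate")
        behind = min(pointers[i] for i in active)
        needed = sorted({reads[i][pointers[i]] for i in active
                         if pointers[i] == behind})
        base = needed[0]
        disp.append(base)
        for i in active:
            r, p = reads[i], pointers[i]
            k = 0
            while p + k < len(r) and r[p + k] == base:
                k += 1
            pointers[i] = p + k
    return "".join(disp)


def _converted_templates(config: AssayConfig) -> dict[tuple[str, str], str]:
    """Converted full-length template per (locus_key, state) with
    locus_key in {'a','b'} (pair) or {'r'} (single region) and state in
    {'m','u'}."""
    out: dict[tuple[str, str], str] = {}
    if config.pair is not None:
        loci = {"a": config.pair.paralog_a, "b": config.pair.paralog_b}
    elif config.region is not None:
        loci = {"r": config.region}
    else:
        raise AssayConfigError("assay has neither a paralog pair nor a region")
    for key, seq in loci.items():
        out[(key, "m")] = bisulfite_convert(seq, MethylationPattern.methylated()).bases
        out[(key, "u")] = bisulfite_convert(seq, MethylationPattern.unmethylated()).bases
    return out


def map_dispensation_positions(config: AssayConfig) -> tuple[VariablePosition, ...]:
    """Translate dispensation slots into the variable-position map.

    Each pure template is sequenced noiselessly under the configured
    dispensation order(s); every alignment column whose expected
    incorporation differs across templates becomes a variable position:
    CpG columns (C/T slots, shared or paralog-specific with per-paralog CpG
    numbers), paralog-marker columns (constant within a paralog, different
    between paralogs), and shifted-CpG columns (mapped but excluded from
    proportion estimation by default). Pure function of the config.
    """
    if not config.windows:
        raise AssayConfigError(f"assay {config.name!r} has no sequencing windows")
    conv = _converted_templates(config)
    duplex = config.pair is not None

    if duplex:
        sites_a = find_cpg_sites(config.pair.paralog_a)
        sites_b = find_cpg_sites(config.pair.paralog_b)
    else:
        sites_a = find_cpg_sites(config.region)
        sites_b = []
    ord_a = {s: i + 1 for i, s in enumerate(sites_a)}
    ord_b = {s: i + 1 for i, s in enumerate(sites_b)}
    shift_cols = _shift_columns(set(sites_a), set(sites_b))

    positions: list[VariablePosition] = []
    for p_idx, ((w0, w1), disp) in enumerate(
            zip(config.windows, config.dispensations), start=1):
        reads = {key: tmpl[w0:w1] for key, tmpl in conv.items()}
        slot_of = {}
        for key, read in reads.items():
            _, slots, consumed = template_walk(read, disp.nucleotides)
            if consumed < len(read):
                raise StallError(
                    f"dispensation for sequencing primer {p_idx} of assay "
                    f"{config.name!r} stalls at window column {consumed} "
                    f"(template {key[0]}/{key[1]} next base "
                    f"{read[consumed]!r})"
                )
            slot_of[key] = slots

        units = _window_units(config, reads, slot_of, w0, w1,
                              ord_a, ord_b, shift_cols, duplex)
        units.sort(key=lambda u: min(min(v) for v in
                                     u["dispensation_indices"].values()))
        for i, u in enumerate(units, start=1):
            positions.append(VariablePosition(pyrogram_index=i, primer=p_idx, **u))
    return tuple(positions)


def _window_units(config, reads, slot_of, w0, w1, ord_a, ord_b,
                  shift_cols, duplex) -> list[dict]:
    """Group variable columns of one sequencing window into positions."""
    keys = list(reads)
    n = w1 - w0
    units: list[dict] = []
    shift_unit_cols: dict[frozenset, list[int]] = {}

    def slots_where(predicate) -> tuple[int, ...]:
        got = set()
        for key in keys:
            for j in range(n):
                if predicate(key, j):
                    s = slot_of[key][j]
                    if s >= 0:
                        got.add(int(s))
        return tuple(sorted(got))

    for j in range(n):
        col = j + w0
        bases = {key: reads[key][j] for key in keys}
        if len(set(bases.values())) == 1 and col not in shift_cols:
            continue
        a_cpg = col in ord_a
        b_cpg = col in ord_b
        if col in shift_cols:
            # accumulated into one unit per contiguous shift run below
            continue
        if a_cpg or b_cpg:
            c_slots, t_slots = set(), set()
            for key in keys:
                locus, state = key
                owns = (locus == "a" and a_cpg) or (locus == "b" and b_cpg) \
                    or (locus == "r" and a_cpg)
                if not owns:
                    continue
                s = int(slot_of[key][j])
                if s < 0:
                    continue
                (c_slots if state == "m" else t_slots).add(s)
            if not c_slots or not t_slots:
                continue
            if not duplex:
                specificity = None
            elif a_cpg and b_cpg:
                specificity = "shared"
            elif a_cpg:
                specificity = "a_specific"
            else:
                specificity = "b_specific"
            units.append(dict(
                kind="cpg",
                dispensation_indices={"variant": tuple(sorted(c_slots)),
                                      "reference": tuple(sorted(t_slots))},
                cpg_number_a=ord_a.get(col),
                cpg_number_b=ord_b.get(col),
                specificity=specificity,
                column=col,
            ))
        elif duplex:
            # paralog-marker column: constant within each paralog
            ba = {reads[("a", s)][j] for s in "mu"}
            bb = {reads[("b", s)][j] for s in "mu"}
            if len(ba) != 1 or len(bb) != 1:
                continue  # methylation-dependent without a CpG: unmappable
            base_a, base_b = ba.pop(), bb.pop()
            slots_a = tuple(sorted({int(slot_of[("a", s)][j]) for s in "mu"
                                    if slot_of[("a", s)][j] >= 0}))
            slots_b = tuple(sorted({int(slot_of[("b", s)][j]) for s in "mu"
                                    if slot_of[("b", s)][j] >= 0}))
            if not slots_a or not slots_b:
                continue
            if base_a == "A" and base_b != "A":
                marker_for = "a"
            elif base_b == "A":
                marker_for = "b"
            else:
                marker_for = "a" if base_a in "AG" else "b"
            variant, reference = ((slots_a, slots_b) if marker_for == "a"
                                  else (slots_b, slots_a))
            units.append(dict(
                kind="paralog_marker",
                dispensation_indices={"variant": variant, "reference": reference},
                marker_for=marker_for,
                column=col,
            ))

    # one unit per contiguous run of shift columns inside the window
    in_window_shift = sorted(c for c in shift_cols if w0 <= c < w1)
    runs: list[list[int]] = []
    for c in in_window_shift:
        if runs and c == runs[-1][-1] + 1:
            runs[-1].append(c)
        else:
            runs.append([c])
    for run in runs:
        c_slots, t_slots = set(), set()
        num_a = num_b = None
        for col in run:
            j = col - w0
            if col in ord_a:
                num_a = ord_a[col]
            if col in ord_b:
                num_b = ord_b[col]
            for key in keys:
                locus, state = key
                owns = (locus == "a" and col in ord_a) or \
                    (locus == "b" and col in ord_b)
                if not owns:
                    continue
                s = int(slot_of[key][j])
                if s < 0:
                    continue
                (c_slots if state == "m" else t_slots).add(s)
        if not c_slots or not t_slots:
            continue
        units.append(dict(
            kind="cpg_shift",
            dispensation_indices={"variant": tuple(sorted(c_slots)),
                                  "reference": tuple(sorted(t_slots))},
            cpg_number_a=num_a,
            cpg_number_b=num_b,
            column=run[0],
        ))
    return units


@dataclass(frozen=True)
class CheckResult:
    name: str
    passed: bool
    message: str = ""


@dataclass(frozen=True)
class AssayReport:
    checks: tuple[CheckResult, ...]

    @property
    def ok(self) -> bool:
        return all(c.passed for c in self.checks)

    @property
    def failures(self) -> tuple[CheckResult, ...]:
        return tuple(c for c in self.checks if not c.passed)

    def to_dict(self) -> dict:
        return {"ok": self.ok,
                "checks": [{"name": c.name, "passed": c.passed,
                            "message": c.message} for c in self.checks]}


def validate_assay(config: AssayConfig) -> AssayReport:
    """Run soft consistency checks on an assay configuration.

    Soft failures are reported, never raised: primer presence, primer
    binding on each converted template (mismatch counts per paralog and
    methylation state), CpG coverage by the sequencing windows, and
    presence of at least one marker per paralog (skipped for single-locus
    assays). A structurally malformed config raises
    :class:`~paralogmeth.errors.AssayConfigError` before any check runs.
    """
    if not isinstance(config, AssayConfig):
        raise AssayConfigError("validate_assay expects an AssayConfig")
    checks: list[CheckResult] = []

    p = config.primers
    checks.append(CheckResult("forward_primer_present", p.forward is not None))
    checks.append(CheckResult("reverse_primer_present", p.reverse is not None))
    checks.append(CheckResult(
        "sequencing_primer_present", len(p.sequencing) >= 1,
        "" if p.sequencing else "no sequencing primer defined"))

    templates = config.assay_sequences
    if templates and p.forward is not None and p.reverse is not None:
        for label, seq in templates.items():
            for state, pattern in (("methylated", MethylationPattern.methylated()),
                                   ("unmethylated", MethylationPattern.unmethylated())):
                conv = bisulfite_convert(seq, pattern)
                for pname, primer, strand in (("forward", p.forward, "+"),
                                              ("reverse", p.reverse, "-")):
                    hits = match_primer(primer, conv, strand, config.max_mismatch)
                    ok = bool(hits)
                    msg = (f"best hit mismatches={hits[0].mismatch_count}" if hits
                           else f"no site within {config.max_mismatch} mismatches")
                    checks.append(CheckResult(
                        f"{pname}_primer_on_{label}_{state}", ok, msg))
    elif not templates:
        checks.append(CheckResult(
            "template_sequences_attached", True,
            "no template attached; sequence-level checks skipped"))

    if templates and config.windows:
        covered = set()
        for w0, w1 in config.windows:
            covered.update(range(w0, w1))
        missing: list[str] = []
        for label, seq in templates.items():
            lo = len(p.forward) if p.forward else 0
            hi = len(seq) - (len(p.reverse) if p.reverse else 0)
            for i, site in enumerate(find_cpg_sites(seq), start=1):
                if lo <= site < hi and site not in covered:
                    missing.append(f"{label} CpG {i}")
        checks.append(CheckResult(
            "cpgs_covered_by_windows", not missing,
            "uncovered: " + ", ".join(missing) if missing else ""))

    if config.pair is not None and config.windows:
        try:
            positions = map_dispensation_positions(config)
        except StallError as exc:
            checks.append(CheckResult("dispensation_consumes_windows", False, str(exc)))
        else:
            checks.append(CheckResult("dispensation_consumes_windows", True))
            for locus in ("a", "b"):
                n = sum(1 for v in positions
                        if v.kind == "paralog_marker" and v.marker_for == locus)
                label = {"a": config.pair.label_a, "b": config.pair.label_b}[locus]
                checks.append(CheckResult(
                    f"marker_present_for_{label}", n >= 1,
                    f"{n} marker position(s)"))
    return AssayReport(tuple(checks))
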