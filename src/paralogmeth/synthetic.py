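"""Seeded synthetic-data generators.

These emulate the study geometry of a duplex bisulfite assay on two
homologous paralogs: a ~230 bp window with ~24 CpGs in paralog A and ~21
in paralog B, ~95% sequence identity, post-conversion differences
concentrated at CpGs (CpG-disrupting C->T edits), exactly one engineered
marker base per paralog, one paralog-B-specific CpG inside the sequenced
window, two paralog-B CpGs under the reverse primer (so the reverse primer
shows one mismatch on unmethylated and three on methylated B product), and
one shifted CpG that sits in a G run and is deliberately awkward to
quantify.

Every feature is placed in a homopolymer-isolated context (flanking bases
chosen from {A, G}) so that, with noise off, each measured dispensation
slot receives signal from exactly one alignment column and all downstream
estimates are exact. The generated truth object records every engineered
feature, which fully determines the expected noiseless output of every
downstream operation.

All randomness flows through one seeded generator; a fixed seed gives
byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .assay import AssayConfig, ParalogPair, Primers, design_dispensation
from .errors import SequenceError
from .hrm import MeltCurve, MeltSpecies, simulate_melt
from .pyrogram import DispensationOrder, Pyrogram, TemplateMix, simulate_pyrogram
from .sequences import (
    MethylationPattern,
    NucleotideSequence,
    bisulfite_convert,
    find_cpg_sites,
    pairwise_identity,
)

#: default seed for the shipped preset fixture
DEFAULT_SEED = 714

_FEATURE_SPAN = {"cpg": 3, "marker_a": 3, "marker_b": 3, "b_new": 3, "shift": 5}


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth of a generated paralog pair.

    Columns are 0-based on the shared assay window. ``disrupted_ordinals``
    are the paralog-A CpG numbers whose cytosine is replaced by T in
    paralog B (A-specific CpGs); ``b_new_columns`` hold CpGs present only
    in B. ``windows`` and primer lengths record the assay layout used by
    :func:`build_assay`.
    """

    seed: int
    length: int
    marker_a_column: int | None
    marker_b_column: int | None
    disrupted_ordinals: tuple[int, ...]
    disrupted_columns: tuple[int, ...]
    b_new_columns: tuple[int, ...]
    shift_columns: tuple[int, ...]
    rev_constant_column: int | None
    rev_b_cpg_columns: tuple[int, ...]
    cpg_sites_a: tuple[int, ...]
    cpg_sites_b: tuple[int, ...]
    identity_percent: float
    fwd_len: int
    rev_len: int
    seq_spans: tuple[tuple[int, int], ...]
    windows: tuple[tuple[int, int], ...]


def _place_features(rng, seq: list, feats: Sequence[str], w0: int, w1: int,
                    b_edits: dict, truth: dict) -> None:
    """Write features into ``seq`` between w0 and w1; record edits/truth."""
    span_total = sum(_FEATURE_SPAN[f] for f in feats)
    slack = (w1 - w0) - span_total
    if slack < len(feats):
        raise SequenceError(
            f"window of {w1 - w0} bp cannot hold {len(feats)} features "
            f"({span_total} bp plus separation)"
        )
    gap = slack // (len(feats) + 1)
    extra = slack - gap * (len(feats) + 1)
    cursor = w0
    for i, f in enumerate(feats):
        cursor += gap + (1 if i < extra else 0)
        p = cursor + 1  # feature anchor; cursor is the left flank
        if f == "cpg":
            seq[cursor] = rng.choice(["A", "G"])
            seq[p] = "C"
            seq[p + 1] = "G"
            truth.setdefault("cpg_anchor_cols", []).append(p)
        elif f in ("marker_a", "marker_b"):
            seq[cursor] = "G"
            seq[p + 1] = "G"
            if f == "marker_a":
                seq[p] = "A"
                b_edits[p] = "T"
                truth["marker_a_column"] = p
            else:
                seq[p] = "T"
                b_edits[p] = "A"
                truth["marker_b_column"] = p
        elif f == "b_new":
            seq[cursor] = rng.choice(["A", "G"])
            seq[p] = "T"
            seq[p + 1] = "G"
            b_edits[p] = "C"
            truth.setdefault("b_new_columns", []).append(p)
        elif f == "shift":
            # A: C C G G (CpG at p+1); B: C G G G (CpG at p)
            seq[cursor] = rng.choice(["A", "G"])
            seq[p] = "C"
            seq[p + 1] = "C"
            seq[p + 2] = "G"
            seq[p + 3] = "G"
            b_edits[p + 1] = "G"
            truth["shift_columns"] = (p, p + 1, p + 2)
        cursor += _FEATURE_SPAN[f]


def generate_paralog_pair(
    seed: int = DEFAULT_SEED,
    length: int = 230,
    target_identity_percent: float = 95.0,
    n_cpgs: int = 24,
    n_markers_per_paralog: int = 1,
    n_disrupting: int | None = None,
    n_seq_primers: int = 2,
    fwd_len: int = 27,
    rev_len: int = 22,
    seq_len: int = 18,
    label_a: str = "A",
    label_b: str = "B",
) -> tuple[ParalogPair, SyntheticTruth]:
    """Generate a homologous paralog pair with engineered, known geometry.

    ``n_cpgs`` counts paralog-A CpGs including the shifted one. Paralog B is
    derived from A by substitutions biased toward CpG-disrupting C->T
    transitions; ``n_disrupting`` defaults to whatever brings the genomic
    identity closest to ``target_identity_percent``. The achieved identity
    must land within one percentage point of the target, else the parameter
    combination is rejected.

    With ``n_markers_per_paralog == 0`` and a 100% identity target the two
    sequences are identical (deconvolution impossible by construction).
    """
    if length < 50:
        raise SequenceError("length must be at least 50 bp")
    if n_markers_per_paralog not in (0, 1):
        raise SequenceError("n_markers_per_paralog must be 0 or 1")
    rng = np.random.default_rng(seed)

    identical = n_markers_per_paralog == 0 and target_identity_percent >= 100.0
    with_extras = not identical and length >= 180
    with_shift = with_extras
    with_b_new = with_extras
    with_rev_edits = with_extras and rev_len >= 16

    n_regular = n_cpgs - (1 if with_shift else 0)
    structural = (2 * n_markers_per_paralog + (1 if with_b_new else 0)
                  + (1 if with_shift else 0) + (3 if with_rev_edits else 0))
    if n_disrupting is None:
        target_edits = round(length * (1.0 - target_identity_percent / 100.0))
        n_disrupting = 0 if identical else min(
            max(target_edits - structural, 1 if n_regular else 0), n_regular)
    if n_disrupting > n_regular:
        raise SequenceError("cannot disrupt more CpGs than exist")

    # ---- feature order: markers and special CpGs early, like the assay
    feats: list[str] = ["cpg"] * n_regular
    if n_markers_per_paralog:
        feats.insert(min(2, len(feats)), "marker_a")
    if with_b_new:
        feats.insert(min(3, len(feats)), "b_new")
    if n_markers_per_paralog:
        feats.insert(min(8, len(feats)), "marker_b")
    if with_shift:
        feats.insert(min(11, len(feats)), "shift")

    n_windows = max(1, n_seq_primers)
    interior = length - fwd_len - rev_len - n_windows * seq_len
    if interior <= 0:
        raise SequenceError("length too short for the primer layout")
    if n_windows == 2:
        # keep every special feature in the first window
        k = max(i for i, f in enumerate(feats) if f != "cpg") + 1 \
            if any(f != "cpg" for f in feats) else len(feats) // 2
        k = max(k, round(len(feats) * 0.58))
        splits = [feats[:k], feats[k:]]
    else:
        splits = [feats]
    need = [sum(_FEATURE_SPAN[f] for f in fs) + len(fs) + 1 for fs in splits]
    if sum(need) > interior:
        raise SequenceError(
            f"{length} bp cannot hold {n_cpgs} CpGs plus engineered features"
        )
    slack = interior - sum(need)
    w_lens = [need[i] + (slack * need[i]) // sum(need) for i in range(len(splits))]
    w_lens[-1] += interior - sum(w_lens)

    seq: list = [None] * length
    b_edits: dict[int, str] = {}
    truth: dict = {}
    cursor = fwd_len
    seq_spans: list[tuple[int, int]] = []
    windows: list[tuple[int, int]] = []
    for fs, wl in zip(splits, w_lens):
        seq_spans.append((cursor, cursor + seq_len))
        cursor += seq_len
        w0, w1 = cursor, cursor + wl
        windows.append((w0, w1))
        _place_features(rng, seq, fs, w0, w1, b_edits, truth)
        cursor = w1

    rev_start = length - rev_len
    assert cursor == rev_start
    if with_rev_edits:
        p = rev_start + 2
        seq[p] = "G"
        b_edits[p] = "A"
        truth["rev_constant_column"] = p
        rev_cols = []
        for p in (rev_start + 6, rev_start + 12):
            seq[p] = "T"
            seq[p + 1] = "G"
            b_edits[p] = "C"
            rev_cols.append(p)
        truth["rev_b_cpg_columns"] = tuple(rev_cols)

    # ---- fill remaining positions without creating CpGs anywhere
    for i in range(length):
        if seq[i] is not None:
            continue
        allowed = {"A", "C", "G", "T"}
        prev = {seq[i - 1], b_edits.get(i - 1, seq[i - 1])} if i > 0 else set()
        nxt = {seq[i + 1], b_edits.get(i + 1, seq[i + 1])} if i + 1 < length else set()
        if "C" in prev:
            allowed.discard("G")
        if "G" in nxt:
            allowed.discard("C")
        seq[i] = rng.choice(sorted(allowed))

    bases_a = "".join(seq)
    bases_b = "".join(b_edits.get(i, b) for i, b in enumerate(bases_a))
    a = NucleotideSequence(id=label_a, bases=bases_a)
    b = NucleotideSequence(id=label_b, bases=bases_b)

    # ---- pick CpGs to disrupt and apply the C->T edits to B
    sites_a = find_cpg_sites(a)
    ord_of = {s: i + 1 for i, s in enumerate(sites_a)}
    shift_cols = truth.get("shift_columns", ())
    regular_sites = [s for s in sites_a if s not in shift_cols]
    disrupted_sites = sorted(
        rng.choice(regular_sites, size=n_disrupting, replace=False).tolist()
    ) if n_disrupting else []
    for s in disrupted_sites:
        bases_b = bases_b[:s] + "T" + bases_b[s + 1:]
    b = NucleotideSequence(id=label_b, bases=bases_b)
    pair = ParalogPair(paralog_a=a, paralog_b=b)
    identity = pairwise_identity(a, b).percent
    if abs(identity - target_identity_percent) > 1.0:
        raise SequenceError(
            f"achieved identity {identity:.2f}% misses target "
            f"{target_identity_percent}% by more than 1 point; adjust "
            f"n_disrupting or target"
        )

    return pair, SyntheticTruth(
        seed=seed,
        length=length,
        marker_a_column=truth.get("marker_a_column"),
        marker_b_column=truth.get("marker_b_column"),
        disrupted_ordinals=tuple(ord_of[s] for s in disrupted_sites),
        disrupted_columns=tuple(disrupted_sites),
        b_new_columns=tuple(truth.get("b_new_columns", ())),
        shift_columns=tuple(shift_cols),
        rev_constant_column=truth.get("rev_constant_column"),
        rev_b_cpg_columns=tuple(truth.get("rev_b_cpg_columns", ())),
        cpg_sites_a=tuple(sites_a),
        cpg_sites_b=tuple(find_cpg_sites(b)),
        identity_percent=identity,
        fwd_len=fwd_len,
        rev_len=rev_len,
        seq_spans=tuple(seq_spans),
        windows=tuple(windows),
    )


def build_assay(pair: ParalogPair, truth: SyntheticTruth,
                name: str = "synthetic-duplex") -> AssayConfig:
    """Derive a complete assay configuration from a generated pair.

    Primers are taken from the unmethylated converted paralog-A sequence
    (primer zones are engineered CpG- and edit-free, so they bind every
    template state); the dispensation order per sequencing window is
    designed against all four pure converted templates.
    """
    conv_u = bisulfite_convert(pair.paralog_a, MethylationPattern.unmethylated())
    fwd = NucleotideSequence(id=f"{name}-F", bases=conv_u.bases[:truth.fwd_len])
    rev = NucleotideSequence(
        id=f"{name}-R",
        bases=conv_u.subsequence(truth.length - truth.rev_len, truth.length)
        .reverse_complement().bases,
    )
    seqp = tuple(
        NucleotideSequence(id=f"{name}-S{i + 1}", bases=conv_u.bases[s0:s1])
        for i, (s0, s1) in enumerate(truth.seq_spans)
    )
    templates = _pure_templates(pair)
    dispensations = []
    for w0, w1 in truth.windows:
        reads = [t.bases[w0:w1] for t in templates.values()]
        dispensations.append(DispensationOrder(design_dispensation(reads)))
    return AssayConfig(
        name=name,
        primers=Primers(forward=fwd, reverse=rev, sequencing=seqp),
        dispensations=tuple(dispensations),
        pair=pair,
        windows=truth.windows,
    )


def _pure_templates(pair: ParalogPair) -> dict[tuple[str, str], NucleotideSequence]:
    return {
        ("a", "m"): bisulfite_convert(pair.paralog_a, MethylationPattern.methylated()),
        ("a", "u"): bisulfite_convert(pair.paralog_a, MethylationPattern.unmethylated()),
        ("b", "m"): bisulfite_convert(pair.paralog_b, MethylationPattern.methylated()),
        ("b", "u"): bisulfite_convert(pair.paralog_b, MethylationPattern.unmethylated()),
    }


def template_mix(pair: ParalogPair, window: tuple[int, int],
                 p_a: float, methylation: float,
                 methylation_b: float | None = None) -> TemplateMix:
    """Four-template ensemble for one sequencing window.

    ``p_a`` is the paralog-A fraction of the product pool and
    ``methylation`` the per-strand methylation probability, both in [0, 1].
    Methylation applies to both paralogs unless ``methylation_b`` is given.
    Mixing the two pure templates of a paralog at weight ``m`` reproduces
    the way wet-lab standards are prepared (mixtures of fully methylated
    and fully unmethylated DNA).
    """
    if not 0.0 <= p_a <= 1.0 or not 0.0 <= methylation <= 1.0:
        raise SequenceError("p_a and methylation must be fractions in [0, 1]")
    m_a = methylation
    m_b = methylation if methylation_b is None else methylation_b
    w0, w1 = window
    t = _pure_templates(pair)
    members = [
        (t[("a", "m")].subsequence(w0, w1, id="A|m"), p_a * m_a),
        (t[("a", "u")].subsequence(w0, w1, id="A|u"), p_a * (1.0 - m_a)),
        (t[("b", "m")].subsequence(w0, w1, id="B|m"), (1.0 - p_a) * m_b),
        (t[("b", "u")].subsequence(w0, w1, id="B|u"), (1.0 - p_a) * (1.0 - m_b)),
    ]
    return TemplateMix.from_pairs(members)


@dataclass(frozen=True)
class StandardSample:
    """One simulated standard: its nominal level, truth, and raw data."""

    level: float
    p_a: float
    pyrograms: tuple[Pyrogram, ...]
    melt: MeltCurve


@dataclass(frozen=True)
class StandardSet:
    samples: tuple[StandardSample, ...]
    seed: int
    noise_sd: float


def generate_standard_set(
    pair: ParalogPair,
    config: AssayConfig,
    levels: Sequence[float] = (0.0, 25.0, 50.0, 75.0, 100.0),
    p_a: float = 0.5,
    noise_sd: float = 0.0,
    seed: int = DEFAULT_SEED,
    tm_unmethylated: float = 79.9,
    tm_methylated: float = 81.3,
    melt_grid: tuple[float, float, float] = (75.0, 86.0, 0.1),
) -> StandardSet:
    """Simulate the standard series (0/25/50/75/100% methylation).

    Each level mixes methylated and unmethylated templates of both paralogs
    at the given paralog ratio, yielding one pyrogram per sequencing primer
    plus a melt curve (methylated amplicons are GC richer after conversion
    and melt higher). All sub-simulations draw seeds from one generator
    seeded with ``seed``.
    """
    rng = np.random.default_rng(seed)
    samples = []
    for level in levels:
        m = level / 100.0
        pyros = []
        for (w0, w1), disp in zip(config.windows, config.dispensations):
            sub = int(rng.integers(0, 2**31 - 1))
            mix = template_mix(pair, (w0, w1), p_a, m)
            pyros.append(simulate_pyrogram(mix, disp, noise_sd=noise_sd, seed=sub))
        melt = simulate_melt(
            [MeltSpecies("unmethylated", tm_unmethylated, weight=1.0 - m),
             MeltSpecies("methylated", tm_methylated, weight=m)],
            noise_sd=noise_sd * 0.01 if noise_sd else 0.0,
            seed=int(rng.integers(0, 2**31 - 1)),
            grid=melt_grid,
            sample_id=f"std{level:g}",
        )
        samples.append(StandardSample(level=float(level), p_a=p_a,
                                      pyrograms=tuple(pyros), melt=melt))
    return StandardSet(samples=tuple(samples), seed=seed, noise_sd=noise_sd)


def generate_melt_standards(
    levels: Sequence[float] = (0.0, 25.0, 50.0, 75.0),
    tm_unmethylated: float = 79.9,
    tm_methylated: float = 81.3,
    baseline: tuple[float, float] = (0.0, 0.0),
    noise_sd: float = 0.0,
    seed: int = DEFAULT_SEED,
    grid: tuple[float, float, float] = (75.0, 86.0, 0.1),
) -> dict[float, MeltCurve]:
    """Melt curves for a methylation-standard series of a single locus."""
    rng = np.random.default_rng(seed)
    out = {}
    for level in levels:
        m = level / 100.0
        out[float(level)] = simulate_melt(
            [MeltSpecies("unmethylated", tm_unmethylated, weight=1.0 - m),
             MeltSpecies("methylated", tm_methylated, weight=m)],
            baseline=baseline,
            noise_sd=noise_sd,
            seed=int(rng.integers(0, 2**31 - 1)),
            grid=grid,
            sample_id=f"std{level:g}",
        )
    return out


def exon2_like_fixture(seed: int = DEFAULT_SEED):
    """The shipped preset: a 230 bp duplex pair with 24/21 CpGs, one marker
    per paralog, ~95% identity, two sequencing primers — the geometry of a
    CDKN2A/CDKN2B exon-2 style assay. Returns ``(pair, truth, config)``."""
    pair, truth = generate_paralog_pair(
        seed=seed, length=230, target_identity_percent=95.0, n_cpgs=24,
        n_markers_per_paralog=1, n_disrupting=6, n_seq_primers=2,
    )
    config = build_assay(pair, truth, name="exon2-like")
    return pair, truth, config
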