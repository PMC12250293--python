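"""Pyrogram simulation and per-position quantification.

Pyrosequencing dispenses nucleotides in a programmed order; each template
molecule incorporates the full homopolymer run of the dispensed base at its
current position (or nothing), and the light signal of a dispensation is
proportional to the number of bases incorporated across the template
ensemble. Heights here are in expected-incorporation units: 1.0 means one
base incorporated in every template. The downstream analysis consumes only
relative peak ratios, so no light-intensity calibration is modeled.

The noise model is i.i.d. Gaussian per dispensation plus an optional linear
signal-decay factor over dispensation index (off by default), with final
heights clipped at zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np

from .errors import AssayConfigError, SequenceError, UndefinedSignalError
from .sequences import NucleotideSequence

_DISP_ALPHABET = frozenset("ACGT")


@dataclass(frozen=True)
class DispensationOrder:
    """The programmed sequence of nucleotide additions."""

    nucleotides: str

    def __post_init__(self) -> None:
        if not self.nucleotides:
            raise SequenceError("dispensation order is empty")
        bad = set(self.nucleotides) - _DISP_ALPHABET
        if bad:
            raise SequenceError(
                f"dispensation order contains non-ACGT characters: {sorted(bad)}"
            )

    @classmethod
    def from_string(cls, text: str) -> "DispensationOrder":
        """Build from free text, stripping hyphenation/line-break artifacts
        (any character outside ACGT is removed on ingest)."""
        cleaned = "".join(c for c in text.upper() if c in _DISP_ALPHABET)
        return cls(cleaned)

    def __len__(self) -> int:
        return len(self.nucleotides)

    def __iter__(self) -> Iterator[str]:
        return iter(self.nucleotides)

    def __getitem__(self, i):
        return self.nucleotides[i]


@dataclass(frozen=True)
class TemplateMix:
    """A weighted ensemble of read sequences (converted strand downstream of
    the sequencing primer). Weights are fractions summing to one."""

    members: tuple[tuple[NucleotideSequence, float], ...]

    def __post_init__(self) -> None:
        if not self.members:
            raise SequenceError("template mix needs at least one member")
        weights = [w for _, w in self.members]
        if any(w < 0 for w in weights):
            raise SequenceError("template weights must be non-negative")
        if abs(sum(weights) - 1.0) > 1e-9:
            raise SequenceError(f"template weights must sum to 1, got {sum(weights)}")

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[NucleotideSequence, float]]) -> "TemplateMix":
        return cls(tuple(pairs))

    @property
    def reads(self) -> tuple[str, ...]:
        return tuple(seq.bases for seq, _ in self.members)

    @property
    def weights(self) -> np.ndarray:
        return np.array([w for _, w in self.members], dtype=float)


@dataclass(frozen=True)
class QualityFlag:
    level: str  # passed | check | failed
    reason: str = ""

    def __post_init__(self) -> None:
        if self.level not in ("passed", "check", "failed"):
            raise ValueError(f"unknown quality level {self.level!r}")
        if self.level == "failed" and not self.reason:
            raise ValueError("failed quality flag requires a reason")


@dataclass(frozen=True)
class QualityThresholds:
    """Absolute total-signal floors, in expected-incorporation units.

    The vendor software's pass/check/fail criteria are proprietary; these
    are declared defaults, configurable, not a reproduction.
    """

    failed_below: float = 0.1
    check_below: float = 0.3


@dataclass(frozen=True)
class Pyrogram:
    """Peak heights per dispensation, plus simulation provenance."""

    dispensation: DispensationOrder
    heights: tuple[float, ...]
    annotations: tuple = ()
    noise_sd: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if len(self.heights) != len(self.dispensation):
            raise SequenceError("one height per dispensation is required")
        if any(h < 0 for h in self.heights):
            raise SequenceError("peak heights must be non-negative")

    @property
    def height_array(self) -> np.ndarray:
        return np.asarray(self.heights, dtype=float)


def template_walk(read: str, dispensation: str) -> tuple[np.ndarray, np.ndarray, int]:
    """Walk one template through a dispensation order.

    Returns ``(counts, slot_of_pos, consumed)`` where ``counts[i]`` is the
    number of bases the template incorporates at dispensation ``i`` (the
    homopolymer run of the dispensed base at the template pointer),
    ``slot_of_pos[p]`` is the dispensation index that consumed template
    position ``p`` (-1 if never consumed), and ``consumed`` is the final
    pointer.
    """
    counts = np.zeros(len(dispensation), dtype=float)
    slot_of_pos = np.full(len(read), -1, dtype=int)
    ptr = 0
    for i, n in enumerate(dispensation):
        k = 0
        while ptr + k < len(read) and read[ptr + k] == n:
            k += 1
        if k:
            slot_of_pos[ptr:ptr + k] = i
            counts[i] = k
            ptr += k
    return counts, slot_of_pos, ptr


def expected_heights(mix: TemplateMix, dispensation: DispensationOrder) -> np.ndarray:
    """Noiseless pyrogram heights: the weighted sum of per-template runs."""
    total = np.zeros(len(dispensation), dtype=float)
    for seq, w in mix.members:
        counts, _, _ = template_walk(seq.bases, dispensation.nucleotides)
        total += w * counts
    return total


def simulate_pyrogram(mix: TemplateMix, dispensation: DispensationOrder,
                      noise_sd: float = 0.0, seed: int | None = None,
                      decay: float = 0.0) -> Pyrogram:
    """Simulate a pyrogram from a weighted template ensemble.

    ``decay`` applies a linear signal-decay factor ``max(0, 1 - decay*i)``
    per dispensation index ``i`` (models the loss of synchrony/signal in
    long runs; off by default). Gaussian noise of standard deviation
    ``noise_sd`` is added per dispensation from a generator seeded with
    ``seed``; heights are clipped at zero. Deterministic given the seed.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    heights = expected_heights(mix, dispensation)
    if decay:
        heights = heights * np.clip(1.0 - decay * np.arange(len(heights)), 0.0, None)
    if noise_sd:
        rng = np.random.default_rng(seed)
        heights = heights + rng.normal(0.0, noise_sd, size=len(heights))
    heights = np.clip(heights, 0.0, None)
    return Pyrogram(dispensation=dispensation, heights=tuple(float(h) for h in heights),
                    noise_sd=noise_sd, seed=seed)


def peak_fraction(pyrogram: Pyrogram, variant_slots: Sequence[int],
                  reference_slots: Sequence[int]) -> float:
    """Variant-base percentage ``100 * h_v / (h_v + h_r)`` over slot sums."""
    h = pyrogram.height_array
    for s in list(variant_slots) + list(reference_slots):
        if not 0 <= s < len(h):
            raise AssayConfigError(f"dispensation slot {s} outside pyrogram")
    hv = float(h[list(variant_slots)].sum())
    hr = float(h[list(reference_slots)].sum())
    total = hv + hr
    if total <= 0.0:
        raise UndefinedSignalError(
            f"no signal at slots {tuple(variant_slots)}+{tuple(reference_slots)}"
        )
    return 100.0 * hv / total


def methylation_from_pyrogram(pyrogram: Pyrogram, positions: Sequence) -> list[tuple[object, float]]:
    """Raw per-CpG methylation percent for positions of kind ``cpg``.

    The variant slots are the C (methylated, retained cytosine) dispensations
    and the reference slots the T dispensations of each position. Returns
    ``(position, percent)`` pairs in the order given.
    """
    out = []
    for pos in positions:
        if getattr(pos, "kind", None) != "cpg":
            continue
        idx = pos.dispensation_indices
        if "variant" not in idx or "reference" not in idx:
            raise AssayConfigError(
                f"position {pos.pyrogram_index} (CpG "
                f"{pos.cpg_number_a or pos.cpg_number_b}) lacks C/T slots"
            )
        out.append((pos, peak_fraction(pyrogram, idx["variant"], idx["reference"])))
    return out


def assess_quality(pyrogram: Pyrogram, position,
                   thresholds: QualityThresholds | None = None) -> QualityFlag:
    """Flag a position by the absolute total signal at its slots."""
    thresholds = thresholds or QualityThresholds()
    h = pyrogram.height_array
    slots = list(position.dispensation_indices.get("variant", ())) + \
        list(position.dispensation_indices.get("reference", ()))
    total = float(h[slots].sum()) if slots else 0.0
    if total < thresholds.failed_below:
        return QualityFlag("failed", f"total signal {total:.3g} below "
                                     f"{thresholds.failed_below}")
    if total < thresholds.check_below:
        return QualityFlag("check", f"total signal {total:.3g} below "
                                    f"{thresholds.check_below}")
    return QualityFlag("passed")
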