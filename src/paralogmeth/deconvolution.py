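"""Paralog deconvolution of co-amplified methylation signals.

When two homologous regions co-amplify, the pyrogram is a weighted overlay
of both paralogs. Marker positions (post-conversion bases unique to one
paralog) yield the proportion of paralog A in the product pool; methylation
read at a paralog-specific CpG is then corrected by that proportion:

    corrected = raw * 100 / proportion_of_owning_paralog

(A-specific CpGs divide by p_A, B-specific CpGs by 100 - p_A.) CpGs present
in both paralogs report a mixed signal and are only reported when the
product pool is nearly pure (reliability tier "full").

Reporting follows the LLOQ/ULOQ rule: PSQ readings at or below 5.00% are
substituted with 2.50%, at or above 95.00% with 97.50%. Raw (pre-LOQ)
values are always carried alongside the reported ones.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from statistics import fmean
from typing import Sequence

import pandas as pd

from .assay import VariablePosition
from .errors import DeconvolutionError
from .pyrogram import (
    Pyrogram,
    QualityFlag,
    QualityThresholds,
    assess_quality,
    peak_fraction,
)


class ReliabilityTier(str, enum.Enum):
    """How much of the CpG panel can be reported at a given purity.

    Below 80% paralog-A product only paralog-specific CpGs are reliable;
    between 80% and 90% (inclusive on both ends) results are moderate; above
    90% the full panel, including shared CpGs, is reported.
    """

    SPECIFIC_ONLY = "specific_only"
    MODERATE = "moderate"
    FULL = "full"


@dataclass(frozen=True)
class AnalysisParams:
    """Quantification-limit and reliability settings (units: percent)."""

    lloq: float = 5.00
    uloq: float = 95.00
    lloq_default: float = 2.50
    uloq_default: float = 97.50
    reliability_low: float = 80.0
    reliability_high: float = 90.0
    loq_on_markers: bool = True
    marker_combination: str = "mean"  # mean | a_only | b_only

    def __post_init__(self) -> None:
        if not (self.lloq_default < self.lloq < self.uloq < self.uloq_default):
            raise ValueError("need lloq_default < lloq < uloq < uloq_default")
        if not self.reliability_low < self.reliability_high:
            raise ValueError("need reliability_low < reliability_high")
        if self.marker_combination not in ("mean", "a_only", "b_only"):
            raise ValueError(f"unknown combination {self.marker_combination!r}")


DEFAULT_PARAMS = AnalysisParams()


@dataclass(frozen=True)
class ParalogProportion:
    """Estimated percentage of paralog A in the PCR product pool.

    ``f_marker_a`` is the fraction of the A-specific base at the A marker,
    ``f_marker_b`` the fraction of the B-specific base at the B marker
    (both as reported, i.e. after LOQ substitution when enabled). The
    ``*_raw`` fields carry the unsubstituted values; ``p_a_raw`` is the
    combination of the raw components.
    """

    p_a: float
    f_marker_a: float | None
    f_marker_b: float | None
    method: str
    p_a_raw: float
    f_marker_a_raw: float | None = None
    f_marker_b_raw: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_a <= 100.0:
            raise DeconvolutionError(f"p_a out of range: {self.p_a}")

    @property
    def p_b(self) -> float:
        return 100.0 - self.p_a


def apply_loq(value: float, params: AnalysisParams = DEFAULT_PARAMS) -> float:
    """Substitute readings beyond the quantification limits.

    Values at or below the LLOQ become ``lloq_default`` (2.50%); at or above
    the ULOQ, ``uloq_default`` (97.50%); anything else passes unchanged.
    Idempotent. Out-of-range input raises ``ValueError``.
    """
    if not 0.0 <= value <= 100.0:
        raise ValueError(f"percent value out of [0, 100]: {value}")
    if value <= params.lloq:
        return params.lloq_default
    if value >= params.uloq:
        return params.uloq_default
    return value


def classify_reliability(proportion: "ParalogProportion | float",
                         params: AnalysisParams = DEFAULT_PARAMS) -> ReliabilityTier:
    """Tier from the paralog-A proportion; 80 and 90 belong to the
    moderate band."""
    p = proportion.p_a if isinstance(proportion, ParalogProportion) else float(proportion)
    if p < params.reliability_low:
        return ReliabilityTier.SPECIFIC_ONLY
    if p <= params.reliability_high:
        return ReliabilityTier.MODERATE
    return ReliabilityTier.FULL


def correct_specific_cpg(raw_percent: float, proportion_percent: float) -> float:
    """Remove the constant-base contribution of the other paralog.

    ``raw * 100 / proportion``, clipped to [0, 100]. A zero (or negative)
    proportion makes the correction undefined and raises
    :class:`~paralogmeth.errors.DeconvolutionError`.
    """
    if proportion_percent <= 0.0:
        raise DeconvolutionError(
            "correction undefined: owning-paralog proportion is zero"
        )
    return min(100.0, max(0.0, raw_percent * 100.0 / proportion_percent))


def _marker_fractions(pyrograms: Sequence[Pyrogram],
                      positions: Sequence[VariablePosition],
                      include_shift: bool = False) -> dict[str, list[float]]:
    fracs: dict[str, list[float]] = {"a": [], "b": []}
    for pos in positions:
        if pos.kind == "cpg_shift" and not include_shift:
            continue
        if pos.kind not in ("paralog_marker",):
            continue
        pyro = pyrograms[pos.primer - 1]
        f = peak_fraction(pyro, pos.dispensation_indices["variant"],
                          pos.dispensation_indices["reference"])
        fracs[pos.marker_for].append(f)
    return fracs


def estimate_paralog_proportion(
    pyrograms: Pyrogram | Sequence[Pyrogram],
    positions: Sequence[VariablePosition],
    params: AnalysisParams = DEFAULT_PARAMS,
) -> ParalogProportion:
    """Estimate p_A from the paralog-marker positions.

    The A-side estimate is the fraction of the A-specific base at the A
    marker(s); the B-side estimate is 100 minus the fraction of the
    B-specific base at the B marker(s). The default combination is their
    unweighted mean (configurable to a single marker). With
    ``params.loq_on_markers`` (default), marker fractions pass the LOQ
    substitution before combination; raw components are carried alongside.
    """
    if isinstance(pyrograms, Pyrogram):
        pyrograms = [pyrograms]
    fracs = _marker_fractions(pyrograms, positions)
    f_a_raw = fmean(fracs["a"]) if fracs["a"] else None
    f_b_raw = fmean(fracs["b"]) if fracs["b"] else None

    need = {"mean": ("a", "b"), "a_only": ("a",), "b_only": ("b",)}
    for side in need[params.marker_combination]:
        if not fracs[side]:
            raise DeconvolutionError(
                f"deconvolution impossible: no marker position for paralog "
                f"{side.upper()} (combination {params.marker_combination!r})"
            )

    def combine(fa, fb):
        if params.marker_combination == "a_only":
            return fa
        if params.marker_combination == "b_only":
            return 100.0 - fb
        return fmean([fa, 100.0 - fb])

    p_raw = combine(f_a_raw, f_b_raw)
    if params.loq_on_markers:
        f_a = apply_loq(f_a_raw, params) if f_a_raw is not None else None
        f_b = apply_loq(f_b_raw, params) if f_b_raw is not None else None
    else:
        f_a, f_b = f_a_raw, f_b_raw
    p = combine(f_a, f_b)
    return ParalogProportion(
        p_a=min(100.0, max(0.0, p)),
        f_marker_a=f_a, f_marker_b=f_b,
        method=params.marker_combination,
        p_a_raw=min(100.0, max(0.0, p_raw)),
        f_marker_a_raw=f_a_raw, f_marker_b_raw=f_b_raw,
    )


@dataclass(frozen=True)
class CpGResult:
    """One CpG row of a methylation profile.

    ``corrected_raw`` is the pre-LOQ corrected value (raw proportion in the
    denominator); ``corrected`` is the reported value (LOQ-substituted
    proportion in the denominator, then LOQ substitution of the result).
    ``corrected`` is ``None`` when the CpG is not analyzable at the sample's
    reliability tier.
    """

    primer: int
    pyrogram_index: int
    specificity: str | None
    cpg_number_a: int | None
    cpg_number_b: int | None
    raw: float
    corrected_raw: float | None
    corrected: float | None
    not_analyzable: bool
    clipped: bool
    quality: QualityFlag

    @property
    def label(self) -> str:
        parts = []
        if self.cpg_number_a is not None:
            parts.append(f"A:CpG{self.cpg_number_a}")
        if self.cpg_number_b is not None:
            parts.append(f"B:CpG{self.cpg_number_b}")
        return "/".join(parts) or "?"


@dataclass(frozen=True)
class MethylationProfile:
    """Per-CpG methylation with the proportion estimate and tier."""

    records: tuple[CpGResult, ...]
    proportion: ParalogProportion | None
    reliability: ReliabilityTier | None
    params: AnalysisParams = field(default=DEFAULT_PARAMS)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            rows.append({
                "primer": r.primer,
                "pos": r.pyrogram_index,
                "cpg_a": r.cpg_number_a,
                "cpg_b": r.cpg_number_b,
                "specificity": r.specificity or "single",
                "raw_percent": r.raw,
                "corrected_percent": r.corrected,
                "not_analyzable": r.not_analyzable,
                "reliability": self.reliability.value if self.reliability else "",
                "quality": r.quality.level,
            })
        return pd.DataFrame(rows)

    def to_dict(self) -> dict:
        d = {
            "records": [
                {
                    "primer": r.primer, "pos": r.pyrogram_index,
                    "cpg_number_a": r.cpg_number_a, "cpg_number_b": r.cpg_number_b,
                    "specificity": r.specificity, "raw": r.raw,
                    "corrected_raw": r.corrected_raw, "corrected": r.corrected,
                    "not_analyzable": r.not_analyzable, "clipped": r.clipped,
                    "quality": r.quality.level,
                } for r in self.records
            ],
            "reliability": self.reliability.value if self.reliability else None,
            "params": {
                "lloq": self.params.lloq, "uloq": self.params.uloq,
                "lloq_default": self.params.lloq_default,
                "uloq_default": self.params.uloq_default,
                "reliability_low": self.params.reliability_low,
                "reliability_high": self.params.reliability_high,
                "loq_on_markers": self.params.loq_on_markers,
                "marker_combination": self.params.marker_combination,
            },
        }
        if self.proportion is not None:
            p = self.proportion
            d["proportion"] = {
                "p_a": p.p_a, "p_a_raw": p.p_a_raw,
                "f_marker_a": p.f_marker_a, "f_marker_b": p.f_marker_b,
                "f_marker_a_raw": p.f_marker_a_raw,
                "f_marker_b_raw": p.f_marker_b_raw,
                "method": p.method,
            }
        else:
            d["proportion"] = None
        return d


def build_profile(
    pyrograms: Pyrogram | Sequence[Pyrogram],
    positions: Sequence[VariablePosition],
    params: AnalysisParams = DEFAULT_PARAMS,
    thresholds: QualityThresholds | None = None,
    include_shift: bool = False,
) -> MethylationProfile:
    """Full deconvolution pipeline for one sample.

    Order: raw per-CpG quantification -> proportion estimate from markers ->
    correction of paralog-specific CpGs (A-specific by p_A, B-specific by
    100 - p_A) -> reliability masking of shared CpGs -> LOQ substitution as
    the final reporting step. Deterministic.

    Single-locus assays (no marker positions declared, ``specificity`` None
    on every CpG) skip the proportion/correction stages and report raw
    methylation with LOQ substitution only.
    """
    if isinstance(pyrograms, Pyrogram):
        pyrograms = [pyrograms]
    cpg_positions = [p for p in positions
                     if p.kind == "cpg" or (include_shift and p.kind == "cpg_shift")]
    duplex = any(p.kind == "paralog_marker" for p in positions) or any(
        p.specificity in ("shared", "a_specific", "b_specific")
        for p in cpg_positions)

    proportion = None
    tier = None
    if duplex:
        proportion = estimate_paralog_proportion(pyrograms, positions, params)
        tier = classify_reliability(proportion, params)

    records: list[CpGResult] = []
    for pos in cpg_positions:
        pyro = pyrograms[pos.primer - 1]
        raw = peak_fraction(pyro, pos.dispensation_indices["variant"],
                            pos.dispensation_indices["reference"])
        quality = assess_quality(pyro, pos, thresholds)
        corrected_raw: float | None = None
        corrected: float | None = None
        not_analyzable = False
        clipped = False

        if not duplex or pos.specificity is None:
            corrected_raw = raw
            corrected = apply_loq(raw, params)
        elif pos.specificity == "a_specific":
            corrected_raw = correct_specific_cpg(raw, proportion.p_a_raw)
            unclipped = raw * 100.0 / proportion.p_a
            clipped = unclipped > 100.0
            corrected = apply_loq(correct_specific_cpg(raw, proportion.p_a), params)
        elif pos.specificity == "b_specific":
            p_b_raw = 100.0 - proportion.p_a_raw
            p_b = 100.0 - proportion.p_a
            if p_b_raw <= 0.0 or p_b <= 0.0:
                not_analyzable = True
            else:
                corrected_raw = correct_specific_cpg(raw, p_b_raw)
                clipped = raw * 100.0 / p_b > 100.0
                corrected = apply_loq(correct_specific_cpg(raw, p_b), params)
        else:  # shared
            if tier is ReliabilityTier.FULL:
                corrected_raw = raw
                corrected = apply_loq(raw, params)
            else:
                not_analyzable = True

        records.append(CpGResult(
            primer=pos.primer, pyrogram_index=pos.pyrogram_index,
            specificity=pos.specificity,
            cpg_number_a=pos.cpg_number_a, cpg_number_b=pos.cpg_number_b,
            raw=raw, corrected_raw=corrected_raw, corrected=corrected,
            not_analyzable=not_analyzable, clipped=clipped, quality=quality,
        ))
    return MethylationProfile(records=tuple(records), proportion=proportion,
                              reliability=tier, params=params)
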