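"""Capillary-electrophoresis genotype calling from peak tables.

Implements the CE threshold regime: a 175-RFU peak amplitude threshold
(PAT) as noise floor, stutter filtering relative to called parent alleles
(n-1, n+1 and n-2nt positions), and the 100/200-RFU heterozygous/
homozygous calling minima. Stutter *observations* are collected on every
surviving stutter-position peak regardless of the filter value, because the
filter governs allele calling only — a real dataset contains stutters both
below and above the filter.
"""

from __future__ import annotations

import enum
import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence, Union

import pandas as pd

from .locus_model import (
    AlleleLabel,
    CopyNumber,
    ExclusionReason,
    LocusDefinition,
    Platform,
    StutterObservation,
    StutterType,
    ThresholdConfig,
)

__all__ = [
    "CEPeak",
    "CELocusCall",
    "CalledPeak",
    "FilterReason",
    "FilteredPeak",
    "RejectedRow",
    "Zygosity",
    "call_ce_locus",
    "collect_ce_stutters",
    "parse_ce_table",
]

CE_TABLE_COLUMNS = ["sample_id", "locus", "allele", "size_bp", "height_rfu", "dye"]


@dataclass(frozen=True)
class CEPeak:
    sample_id: str
    locus: str
    allele: AlleleLabel
    size_bp: float
    height_rfu: float
    dye: str = "B"

    def __post_init__(self) -> None:
        if self.height_rfu <= 0:
            raise ValueError("height_rfu must be positive")


class FilterReason(str, enum.Enum):
    BELOW_PAT = "below_pat"
    BELOW_HET = "below_het"
    BELOW_HOM = "below_hom"
    STUTTER_FILTERED = "stutter_filtered"


class Zygosity(str, enum.Enum):
    SINGLE_PEAK = "single_peak"
    HETEROZYGOUS = "heterozygous"
    MULTI_ALLELIC = "multi_allelic"
    NO_CALL = "no_call"


@dataclass(frozen=True)
class CalledPeak:
    allele: AlleleLabel
    height_rfu: float


@dataclass(frozen=True)
class FilteredPeak:
    peak: CEPeak
    reason: FilterReason
    parent: AlleleLabel | None = None  # set for stutter_filtered peaks


@dataclass
class CELocusCall:
    sample_id: str
    locus: str
    called: list[CalledPeak]
    filtered: list[FilteredPeak]
    zygosity: Zygosity
    n_input_peaks: int

    @property
    def alleles(self) -> list[AlleleLabel]:
        return sorted(p.allele for p in self.called)

    @property
    def surviving_peaks(self) -> int:
        below_pat = sum(1 for f in self.filtered if f.reason is FilterReason.BELOW_PAT)
        return self.n_input_peaks - below_pat


@dataclass(frozen=True)
class RejectedRow:
    row_index: int
    reason: str
    raw: dict


def parse_ce_table(
    source: Union[str, Path, io.TextIOBase]
) -> tuple[list[CEPeak], list[RejectedRow]]:
    """Parse a tab-delimited CE peak export.

    Malformed rows (unparseable allele labels, non-positive heights, missing
    fields) are collected into a rejects report rather than silently dropped.
    A missing required column is a hard format error.
    """
    df = pd.read_csv(source, sep="\t", dtype=str)
    missing = [c for c in CE_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"CE table missing required columns: {missing}")
    peaks: list[CEPeak] = []
    rejects: list[RejectedRow] = []
    for idx, row in df.iterrows():
        raw = row.to_dict()
        try:
            if any(pd.isna(row[c]) for c in CE_TABLE_COLUMNS[:5]):
                raise ValueError("missing field")
            peaks.append(
                CEPeak(
                    sample_id=str(row["sample_id"]),
                    locus=str(row["locus"]),
                    allele=AlleleLabel.parse(row["allele"]),
                    size_bp=float(row["size_bp"]),
                    height_rfu=float(row["height_rfu"]),
                    dye=str(row["dye"]),
                )
            )
        except (ValueError, TypeError) as exc:
            rejects.append(RejectedRow(int(idx), str(exc), raw))
    return peaks, rejects


def _stutter_position(
    parent: AlleleLabel, stype: StutterType, unit: int
) -> AlleleLabel | None:
    """Allele position at which a stutter of ``parent`` would sit."""
    try:
        if stype is StutterType.MINUS_ONE_REPEAT:
            return parent.shift_repeats(-1)
        if stype is StutterType.PLUS_ONE_REPEAT:
            return parent.shift_repeats(+1)
        return parent.shift_nt(-2, unit)
    except ValueError:
        return None


def _stutter_filter_value(
    locus_def: LocusDefinition, stype: StutterType
) -> float | None:
    if stype is StutterType.MINUS_ONE_REPEAT:
        return locus_def.ce_minus_stutter_filter
    if stype is StutterType.PLUS_ONE_REPEAT:
        return locus_def.ce_plus_stutter_filter
    # n-2nt products back-slip by a half repeat; filtered with the minus
    # filter unless a dedicated value is configured
    if locus_def.ce_minus2nt_stutter_filter is not None:
        return locus_def.ce_minus2nt_stutter_filter
    return locus_def.ce_minus_stutter_filter


def call_ce_locus(
    peaks: Sequence[CEPeak],
    locus_def: LocusDefinition,
    thresholds: ThresholdConfig,
    sample_id: str = "",
) -> CELocusCall:
    """Call a genotype for one sample x locus from its CE peaks.

    Order of operations: PAT removal first (signal-to-noise), then stutter
    attribution against taller accepted peaks, then the 100/200-RFU
    het/hom calling minima on the remaining candidate alleles.
    """
    if peaks:
        sids = {p.sample_id for p in peaks}
        loci = {p.locus for p in peaks}
        if len(sids) > 1 or len(loci) > 1:
            raise ValueError("peaks must share one sample and one locus")
        if peaks[0].locus != locus_def.name:
            raise ValueError(
                f"peaks are for locus {peaks[0].locus!r}, not {locus_def.name!r}"
            )
        sample_id = peaks[0].sample_id

    unit = locus_def.repeat_unit_length
    filtered: list[FilteredPeak] = []
    survivors: list[CEPeak] = []
    for p in peaks:
        if p.height_rfu < thresholds.pat_rfu:
            filtered.append(FilteredPeak(p, FilterReason.BELOW_PAT))
        else:
            survivors.append(p)

    # Tallest-first pass: a peak sitting at a stutter position of an already
    # accepted (taller) candidate, with ratio within the locus filter, is a
    # stutter product rather than a candidate allele.
    candidates: list[CEPeak] = []
    for p in sorted(survivors, key=lambda q: (-q.height_rfu, q.allele)):
        parent_hit: tuple[CEPeak, StutterType] | None = None
        for cand in candidates:
            for stype in (
                StutterType.MINUS_ONE_REPEAT,
                StutterType.PLUS_ONE_REPEAT,
                StutterType.MINUS_2NT,
            ):
                pos = _stutter_position(cand.allele, stype, unit)
                if pos != p.allele:
                    continue
                filt = _stutter_filter_value(locus_def, stype)
                if filt is None:
                    continue
                ratio = p.height_rfu / cand.height_rfu * 100.0
                if ratio <= filt:
                    parent_hit = (cand, stype)
                    break
            if parent_hit:
                break
        if parent_hit:
            filtered.append(
                FilteredPeak(p, FilterReason.STUTTER_FILTERED, parent_hit[0].allele)
            )
        else:
            candidates.append(p)

    called: list[CalledPeak] = []
    if len(candidates) == 1:
        p = candidates[0]
        if p.height_rfu >= thresholds.ce_hom_rfu:
            called.append(CalledPeak(p.allele, p.height_rfu))
        else:
            filtered.append(FilteredPeak(p, FilterReason.BELOW_HOM))
    elif len(candidates) >= 2:
        strong = [p for p in candidates if p.height_rfu >= thresholds.ce_het_rfu]
        for p in candidates:
            if p not in strong:
                filtered.append(FilteredPeak(p, FilterReason.BELOW_HET))
        if len(strong) == 1:
            # partner dropped below the het minimum: the lone remainder is
            # held to the homozygous minimum before calling
            p = strong[0]
            if p.height_rfu >= thresholds.ce_hom_rfu:
                called.append(CalledPeak(p.allele, p.height_rfu))
            else:
                filtered.append(FilteredPeak(p, FilterReason.BELOW_HOM))
        else:
            called.extend(CalledPeak(p.allele, p.height_rfu) for p in strong)

    if not called:
        zygosity = Zygosity.NO_CALL
    elif len(called) == 1:
        zygosity = Zygosity.SINGLE_PEAK
    elif len(called) == 2:
        zygosity = Zygosity.HETEROZYGOUS
    else:
        zygosity = Zygosity.MULTI_ALLELIC

    return CELocusCall(
        sample_id=sample_id,
        locus=locus_def.name,
        called=sorted(called, key=lambda c: c.allele),
        filtered=filtered,
        zygosity=zygosity,
        n_input_peaks=len(peaks),
    )


def _copy_labels(alleles: Sequence[AlleleLabel]) -> dict[AlleleLabel, str]:
    letters = "abcdef"
    return {a: letters[i] for i, a in enumerate(sorted(set(alleles)))}


def collect_ce_stutters(
    call: CELocusCall, locus_def: LocusDefinition
) -> list[StutterObservation]:
    """Collect stutter observations around every called parent allele.

    All surviving (>= PAT) peaks at stutter positions contribute, whatever
    the filter said — including peaks that are themselves called alleles,
    which happens at multicopy heterozygotes one repeat apart. Those overlap
    cases are emitted as *excluded* observations so summaries can omit them,
    exactly mirroring the manual exclusion applied at DYS385 a/b and
    DYF387S1.
    """
    unit = locus_def.repeat_unit_length
    heights: dict[AlleleLabel, float] = {}
    for c in call.called:
        heights[c.allele] = heights.get(c.allele, 0.0) + c.height_rfu
    for f in call.filtered:
        if f.reason is not FilterReason.BELOW_PAT:
            heights.setdefault(f.peak.allele, f.peak.height_rfu)

    called_alleles = [c.allele for c in call.called]
    called_set = set(called_alleles)
    multicopy = locus_def.copy_number is CopyNumber.MULTI
    copies = _copy_labels(called_alleles) if multicopy else {}

    out: list[StutterObservation] = []
    for parent in called_alleles:
        parent_h = heights[parent]
        for stype in (
            StutterType.MINUS_ONE_REPEAT,
            StutterType.PLUS_ONE_REPEAT,
            StutterType.MINUS_2NT,
        ):
            pos = _stutter_position(parent, stype, unit)
            if pos is None or pos == parent or pos not in heights:
                continue
            notes = ""
            if (
                stype is StutterType.PLUS_ONE_REPEAT
                and pos not in called_set
                and pos.shift_repeats(+1) in called_set
            ):
                # the same peak sits one repeat below another called allele:
                # the minus interpretation dominates, keep only that one
                continue
            if (
                stype is StutterType.MINUS_ONE_REPEAT
                and pos not in called_set
                and pos.shift_repeats(-1) in called_set
            ):
                notes = "ambiguous_plus_minus"
            excluded = False
            reason = ExclusionReason.NONE
            if stype is StutterType.MINUS_ONE_REPEAT and pos in called_set:
                excluded, reason = True, ExclusionReason.OVERLAPS_SMALLER_ALLELE
            elif stype is StutterType.PLUS_ONE_REPEAT and pos in called_set:
                excluded, reason = True, ExclusionReason.OVERLAPS_LARGER_ALLELE
            out.append(
                StutterObservation(
                    sample_id=call.sample_id,
                    locus=call.locus,
                    platform=Platform.CE,
                    parent_allele=parent,
                    stutter_type=stype,
                    ratio_pct=heights[pos] / parent_h * 100.0,
                    excluded=excluded,
                    exclusion_reason=reason,
                    copy_label=copies.get(parent),
                    notes=notes,
                )
            )
    return out
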