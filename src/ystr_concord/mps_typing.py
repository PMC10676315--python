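"""MPS sequence-based Y-STR typing.

Covers the read-threshold machinery (per-sample 85,000-read gate; per-locus
analytical/interpretation thresholds recalculated on a 650-read basis with
10/30-read floors), bracketed repeat-region nomenclature with microvariant
and isometric-variant handling, iso-allele detection at multicopy loci,
grey-zone candidate flagging, and sequence-exact stutter identification.

Bracket notation is the run-length encoding of the repeat region in
repeat-unit chunks, e.g. ``[TCTA]5 [TCTG]1 [TCTA]5``; expanding the
notation always reproduces the input sequence byte for byte.
"""

from __future__ import annotations

import io
import math
import re
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
    "BracketParseError",
    "CalledSequence",
    "GateResult",
    "IsoAlleleReport",
    "MPSLocusCall",
    "MPSSequenceRecord",
    "RejectedRow",
    "bracket_sequence",
    "call_mps_locus",
    "canonical_stutter_sequence",
    "detect_iso_alleles",
    "expand_bracket",
    "expand_reference",
    "gate_sample",
    "identify_mps_stutters",
    "parse_mps_table",
    "recalc_thresholds",
    "stutter_sequences",
]

MPS_TABLE_COLUMNS = ["sample_id", "locus", "sequence", "reads", "typed_flag"]

_SEQ_RE = re.compile(r"^[ACGT]+$")


class BracketParseError(ValueError):
    """A repeat-region sequence that cannot be reconciled with the locus."""


@dataclass(frozen=True)
class MPSSequenceRecord:
    sample_id: str
    locus: str
    sequence: str
    reads: int
    typed_flag: str = "NO"  # vendor-style label: YES = max-intensity true allele

    def __post_init__(self) -> None:
        if self.reads < 1:
            raise ValueError("reads must be >= 1")
        if not _SEQ_RE.match(self.sequence):
            raise ValueError("sequence must be non-empty over ACGT")


@dataclass(frozen=True)
class SequenceAllele:
    locus: str
    sequence: str
    bracket_notation: str
    length_allele: AlleleLabel
    is_reference_variant: bool


@dataclass(frozen=True)
class RejectedRow:
    row_index: int
    reason: str
    raw: dict


@dataclass(frozen=True)
class GateResult:
    sample_id: str
    total_reads: int
    passed: bool


@dataclass(frozen=True)
class CalledSequence:
    allele: SequenceAllele
    reads: int


@dataclass
class MPSLocusCall:
    sample_id: str
    locus: str
    locus_reads: int
    at_reads: int
    it_reads: int
    called: list[CalledSequence]
    grey_zone_candidates: list[CalledSequence]
    stutter_attributed: list[CalledSequence]
    discarded: list[MPSSequenceRecord]
    qc_flags: set[str] = field(default_factory=set)

    @property
    def alleles(self) -> list[AlleleLabel]:
        return sorted(c.allele.length_allele for c in self.called)


# ---------------------------------------------------------------------------
# sequence nomenclature


def _chunks(sequence: str, unit: int) -> tuple[list[str], str]:
    n_units = len(sequence) // unit
    return (
        [sequence[i * unit : (i + 1) * unit] for i in range(n_units)],
        sequence[n_units * unit :],
    )


def _rle(chunks: Sequence[str]) -> list[tuple[str, int]]:
    runs: list[tuple[str, int]] = []
    for c in chunks:
        if runs and runs[-1][0] == c:
            runs[-1] = (c, runs[-1][1] + 1)
        else:
            runs.append((c, 1))
    return runs


def _format_bracket(runs: Sequence[tuple[str, int]], tail: str) -> str:
    parts = [f"[{m}]{n}" for m, n in runs]
    if tail:
        parts.append(tail)
    return " ".join(parts)


_BRACKET_RE = re.compile(r"\[([ACGT]+)\](\d+)|([ACGT]+)")


def expand_bracket(notation: str) -> str:
    """Expand ``[MOTIF]n`` bracket notation back to the plain sequence."""
    out: list[str] = []
    for token in notation.split():
        m = _BRACKET_RE.fullmatch(token)
        if not m:
            raise BracketParseError(f"bad bracket token: {token!r}")
        if m.group(1) is not None:
            out.append(m.group(1) * int(m.group(2)))
        else:
            out.append(m.group(3))
    return "".join(out)


def expand_reference(
    locus_def: LocusDefinition, allele: Union[AlleleLabel, int, str]
) -> str:
    """Reference repeat-region sequence for a length-based allele.

    Repeat-count variation relative to the reference architecture is carried
    by the primary expandable block (the last expandable counted block);
    fixed blocks keep their reference counts. Microvariant residues append a
    prefix of the primary motif.
    """
    if not isinstance(allele, AlleleLabel):
        allele = AlleleLabel.parse(allele)
    counts = [b.ref_count for b in locus_def.motif_structure]
    primary = locus_def.primary_expandable_block
    others = sum(
        counts[i] for i in locus_def.counted_blocks if i != primary
    )
    primary_count = allele.repeats - others
    if primary_count < 0:
        raise ValueError(
            f"{locus_def.name}: allele {allele} below the fixed repeat count"
        )
    counts[primary] = primary_count
    seq = "".join(
        b.motif * c for b, c in zip(locus_def.motif_structure, counts)
    )
    if allele.partial_nt:
        motif = locus_def.motif_structure[primary].motif
        if allele.partial_nt >= len(motif):
            raise ValueError("partial_nt must be shorter than the repeat unit")
        seq += motif[: allele.partial_nt]
    return seq


def bracket_sequence(sequence: str, locus_def: LocusDefinition) -> SequenceAllele:
    """Type a repeat-region sequence against the locus architecture.

    A structured greedy left-to-right parse is attempted first: fixed blocks
    must match exactly, expandable blocks absorb maximal runs of their
    motif. Sequences that fail the structured parse (isometric variants with
    substituted repeat units) fall back to arithmetic length typing, which
    is only well-defined when every block is counted; anything else is a
    parse error, never a silent call.
    """
    sequence = sequence.strip().upper()
    if not _SEQ_RE.match(sequence):
        raise BracketParseError("sequence must be non-empty over ACGT")
    unit = locus_def.repeat_unit_length
    chunks, tail = _chunks(sequence, unit)
    if not chunks:
        raise BracketParseError(
            f"{locus_def.name}: sequence shorter than one repeat unit"
        )
    runs = _rle(chunks)

    repeats = _structured_repeat_count(chunks, locus_def)
    if repeats is None:
        uncounted = [
            i
            for i in range(len(locus_def.motif_structure))
            if i not in locus_def.counted_blocks
        ]
        if uncounted:
            raise BracketParseError(
                f"{locus_def.name}: sequence does not fit the block structure "
                "and arithmetic typing is ambiguous with uncounted blocks"
            )
        repeats = len(chunks)

    length_allele = AlleleLabel(repeats, len(tail))
    try:
        ref = expand_reference(locus_def, length_allele)
    except ValueError:
        ref = None
    return SequenceAllele(
        locus=locus_def.name,
        sequence=sequence,
        bracket_notation=_format_bracket(runs, tail),
        length_allele=length_allele,
        is_reference_variant=(sequence != ref),
    )


def _structured_repeat_count(
    chunks: Sequence[str], locus_def: LocusDefinition
) -> int | None:
    """Greedy block-wise parse; returns the counted repeat total or None."""
    pos = 0
    counts: list[int] = []
    for block in locus_def.motif_structure:
        if block.expandable:
            k = 0
            while pos < len(chunks) and chunks[pos] == block.motif:
                pos += 1
                k += 1
            counts.append(k)
        else:
            if chunks[pos : pos + block.ref_count] != [block.motif] * block.ref_count:
                return None
            pos += block.ref_count
            counts.append(block.ref_count)
    if pos != len(chunks):
        return None
    return sum(counts[i] for i in locus_def.counted_blocks)


def stutter_sequences(
    parent_sequence: str, locus_def: LocusDefinition, stype: StutterType
) -> set[str]:
    """All sequences one expandable-block repeat shorter/longer than parent.

    Stutter identification is sequence-exact: a candidate is a stutter of a
    parent only if it is *equal* to the parent with exactly one repeat of an
    expandable motif removed (n-1) or added (n+1).
    """
    unit = locus_def.repeat_unit_length
    chunks, tail = _chunks(parent_sequence, unit)
    runs = _rle(chunks)
    expandable_motifs = {
        b.motif for b in locus_def.motif_structure if b.expandable
    }
    delta = -1 if stype is StutterType.MINUS_ONE_REPEAT else +1
    out: set[str] = set()
    for i, (motif, count) in enumerate(runs):
        if motif not in expandable_motifs:
            continue
        if count + delta < 0:
            continue
        new_runs = list(runs)
        new_runs[i] = (motif, count + delta)
        seq = "".join(m * c for m, c in new_runs) + tail
        if seq:
            out.add(seq)
    return out


def canonical_stutter_sequence(
    parent_sequence: str, locus_def: LocusDefinition, stype: StutterType
) -> str:
    """Deterministic stutter product: slip the longest (last) expandable run."""
    unit = locus_def.repeat_unit_length
    chunks, tail = _chunks(parent_sequence, unit)
    runs = _rle(chunks)
    expandable_motifs = {b.motif for b in locus_def.motif_structure if b.expandable}
    best = None
    for i, (motif, count) in enumerate(runs):
        if motif in expandable_motifs and (best is None or count >= runs[best][1]):
            best = i
    if best is None:
        raise ValueError("parent has no expandable-motif run")
    delta = -1 if stype is StutterType.MINUS_ONE_REPEAT else +1
    if runs[best][1] + delta < 0:
        raise ValueError("cannot remove a repeat from an empty run")
    new_runs = list(runs)
    new_runs[best] = (new_runs[best][0], new_runs[best][1] + delta)
    return "".join(m * c for m, c in new_runs) + tail


# ---------------------------------------------------------------------------
# thresholds and calling


def parse_mps_table(
    source: Union[str, Path, io.TextIOBase]
) -> tuple[list[MPSSequenceRecord], list[RejectedRow]]:
    """Parse a tab-delimited MPS per-locus sequence-read table."""
    df = pd.read_csv(source, sep="\t", dtype=str)
    missing = [c for c in MPS_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"MPS table missing required columns: {missing}")
    records: list[MPSSequenceRecord] = []
    rejects: list[RejectedRow] = []
    for idx, row in df.iterrows():
        raw = row.to_dict()
        try:
            if any(pd.isna(row[c]) for c in MPS_TABLE_COLUMNS[:4]):
                raise ValueError("missing field")
            records.append(
                MPSSequenceRecord(
                    sample_id=str(row["sample_id"]),
                    locus=str(row["locus"]),
                    sequence=str(row["sequence"]).upper(),
                    reads=int(row["reads"]),
                    typed_flag=str(row.get("typed_flag", "NO")),
                )
            )
        except (ValueError, TypeError) as exc:
            rejects.append(RejectedRow(int(idx), str(exc), raw))
    return records, rejects


def gate_sample(
    records: Sequence[MPSSequenceRecord],
    thresholds: ThresholdConfig,
    total_reads: int | None = None,
) -> GateResult:
    """Apply the total-sample read-count gate (default >= 85,000 reads).

    The gate operates on the whole sequencing run; when the table at hand
    covers only part of the panel, pass the run total via ``total_reads``.
    """
    sample_id = records[0].sample_id if records else ""
    if total_reads is None:
        total_reads = sum(r.reads for r in records)
    return GateResult(
        sample_id=sample_id,
        total_reads=total_reads,
        passed=total_reads >= thresholds.mps_sample_read_gate,
    )


def recalc_thresholds(
    locus_reads: int,
    locus_def: LocusDefinition,
    thresholds: ThresholdConfig,
) -> tuple[int, int]:
    """Recalculate the per-locus AT/IT in reads from the locus coverage.

    Default rule (``floor650``): percentages are taken of
    ``max(locus_reads, 650)`` and rounded up, which reproduces the printed
    10/30-read floors at the default 1.5%/4.5% (9.75 -> 10, 29.25 -> 30).
    Alternative (``hardfloor``): percentages of the raw locus reads with
    hard minima of 10 and 30 reads.
    """
    if locus_reads < 0:
        raise ValueError("locus_reads must be non-negative")
    basis_floor = thresholds.mps_recalc_basis_reads
    if thresholds.recalc_basis == "hardfloor":
        at = max(math.ceil(locus_def.at_pct / 100.0 * locus_reads), 10)
        it = max(math.ceil(locus_def.it_pct / 100.0 * locus_reads), 30)
    else:
        basis = max(locus_reads, basis_floor)
        at = math.ceil(locus_def.at_pct / 100.0 * basis)
        it = math.ceil(locus_def.it_pct / 100.0 * basis)
    if at >= it:
        it = at + 1
    return at, it


def call_mps_locus(
    records: Sequence[MPSSequenceRecord],
    locus_def: LocusDefinition,
    thresholds: ThresholdConfig,
    sample_id: str = "",
) -> MPSLocusCall:
    """Call sequence-based alleles for one sample x locus.

    Sequences below the analytical threshold are discarded; sequences in
    the open interval (AT, IT) become grey-zone candidates surfaced for
    operator review, never auto-called; sequences at or above the IT are
    called unless attributable as a stutter of a stronger called allele
    (sequence-exact match at a ratio within the locus stutter filter, the
    same filter value serving both stutter directions). A locus whose reads
    never reach the IT is flagged inconclusive (low_coverage_inc).
    """
    if records:
        sids = {r.sample_id for r in records}
        loci = {r.locus for r in records}
        if len(sids) > 1 or len(loci) > 1:
            raise ValueError("records must share one sample and one locus")
        if records[0].locus != locus_def.name:
            raise ValueError(
                f"records are for locus {records[0].locus!r}, not {locus_def.name!r}"
            )
        sample_id = records[0].sample_id

    locus_reads = sum(r.reads for r in records)
    at_reads, it_reads = recalc_thresholds(locus_reads, locus_def, thresholds)

    discarded = [r for r in records if r.reads <= at_reads]
    grey_raw = [r for r in records if at_reads < r.reads < it_reads]
    strong = [r for r in records if r.reads >= it_reads]

    # descending intensity; ties broken longer-allele-first then lexicographic
    strong.sort(key=lambda r: (-r.reads, -len(r.sequence), r.sequence))

    called: list[CalledSequence] = []
    attributed: list[CalledSequence] = []
    for r in strong:
        allele = bracket_sequence(r.sequence, locus_def)
        parent_hit = False
        for c in called:
            for stype in (StutterType.MINUS_ONE_REPEAT, StutterType.PLUS_ONE_REPEAT):
                if r.sequence in stutter_sequences(
                    c.allele.sequence, locus_def, stype
                ):
                    ratio = r.reads / c.reads * 100.0
                    if ratio <= locus_def.mps_stutter_filter:
                        parent_hit = True
                        break
            if parent_hit:
                break
        if parent_hit:
            attributed.append(CalledSequence(allele, r.reads))
        else:
            called.append(CalledSequence(allele, r.reads))

    grey = [
        CalledSequence(bracket_sequence(r.sequence, locus_def), r.reads)
        for r in grey_raw
    ]

    qc: set[str] = set()
    if grey:
        qc.add("grey_zone")
    if not called and locus_reads > 0:
        qc.add("low_coverage_inc")
    if locus_def.copy_number is CopyNumber.MULTI and len(called) >= 2:
        reads = sorted(c.reads for c in called)
        if reads[0] / reads[-1] * 100.0 < thresholds.ilb_threshold_mps:
            qc.add("imbalance")

    return MPSLocusCall(
        sample_id=sample_id,
        locus=locus_def.name,
        locus_reads=locus_reads,
        at_reads=at_reads,
        it_reads=it_reads,
        called=called,
        grey_zone_candidates=grey,
        stutter_attributed=attributed,
        discarded=discarded,
        qc_flags=qc,
    )


@dataclass
class IsoAlleleReport:
    locus: str
    sample_id: str
    iso_allele_pairs: list[tuple[SequenceAllele, SequenceAllele]]
    variant_homozygote: SequenceAllele | None


def detect_iso_alleles(call: MPSLocusCall) -> IsoAlleleReport:
    """Flag iso-alleles: same length-based allele, different sequence.

    At a multicopy locus, a single called sequence that deviates from the
    reference expansion is reported as a variant homozygote — the category
    the vendor software cannot flag and that requires manual review.
    """
    pairs: list[tuple[SequenceAllele, SequenceAllele]] = []
    alleles = [c.allele for c in call.called]
    for i in range(len(alleles)):
        for j in range(i + 1, len(alleles)):
            a, b = alleles[i], alleles[j]
            if a.length_allele == b.length_allele and a.sequence != b.sequence:
                pairs.append(tuple(sorted((a, b), key=lambda s: s.sequence)))
    variant_hom = None
    if len({a.sequence for a in alleles}) == 1 and alleles:
        if alleles[0].is_reference_variant:
            variant_hom = alleles[0]
    return IsoAlleleReport(
        locus=call.locus,
        sample_id=call.sample_id,
        iso_allele_pairs=pairs,
        variant_homozygote=variant_hom,
    )


def _copy_labels(alleles: Sequence[AlleleLabel]) -> dict[AlleleLabel, str]:
    letters = "abcdef"
    return {a: letters[i] for i, a in enumerate(sorted(set(alleles)))}


def identify_mps_stutters(
    records: Sequence[MPSSequenceRecord],
    call: MPSLocusCall,
    locus_def: LocusDefinition,
) -> list[StutterObservation]:
    """Collect sequence-exact stutter observations around called parents.

    Every record above the analytical threshold whose sequence equals a
    called parent's sequence with one expandable repeat removed (n-1) or
    added (n+1) yields an observation, whatever the stutter filter says —
    the filter governs calling, not observation. At heterozygotes one
    repeat apart, the larger allele's minus stutter and the smaller
    allele's plus stutter are emitted as excluded (peak overlap), matching
    the multicopy exclusion rule.
    """
    reads_by_seq: dict[str, int] = {}
    for r in records:
        if r.reads > call.at_reads:
            reads_by_seq[r.sequence] = reads_by_seq.get(r.sequence, 0) + r.reads

    called_lengths = {c.allele.length_allele for c in call.called}
    multicopy = locus_def.copy_number is CopyNumber.MULTI
    copies = (
        _copy_labels([c.allele.length_allele for c in call.called])
        if multicopy
        else {}
    )

    out: list[StutterObservation] = []
    for parent in call.called:
        p_len = parent.allele.length_allele
        for stype in (StutterType.MINUS_ONE_REPEAT, StutterType.PLUS_ONE_REPEAT):
            candidates = stutter_sequences(parent.allele.sequence, locus_def, stype)
            hits = [
                s for s in candidates if s in reads_by_seq and s != parent.allele.sequence
            ]
            if not hits:
                continue
            stutter_reads = sum(reads_by_seq[s] for s in hits)
            delta = -1 if stype is StutterType.MINUS_ONE_REPEAT else +1
            overlap = p_len.shift_repeats(delta) in called_lengths
            if stype is StutterType.MINUS_ONE_REPEAT:
                reason = (
                    ExclusionReason.OVERLAPS_SMALLER_ALLELE
                    if overlap
                    else ExclusionReason.NONE
                )
            else:
                reason = (
                    ExclusionReason.OVERLAPS_LARGER_ALLELE
                    if overlap
                    else ExclusionReason.NONE
                )
            out.append(
                StutterObservation(
                    sample_id=call.sample_id,
                    locus=call.locus,
                    platform=Platform.MPS,
                    parent_allele=p_len,
                    stutter_type=stype,
                    ratio_pct=stutter_reads / parent.reads * 100.0,
                    excluded=overlap,
                    exclusion_reason=reason,
                    copy_label=copies.get(p_len),
                )
            )
    return out
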