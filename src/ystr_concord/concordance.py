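"""CE vs MPS comparison: concordance classification, allele census,
intra-locus balance, and the statistical tests.

The concordance logic follows forensic practice for apparent discordances:
when the platforms disagree in length-based calls but every CE-only allele
matches an MPS grey-zone candidate (signal between the analytical and the
interpretation threshold), the case is classified as an *apparent*
discordance for operator review rather than a true one.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence, Union

import pandas as pd
from scipy import stats

from .ce_typing import CELocusCall
from .locus_model import (
    AlleleLabel,
    BalanceObservation,
    ConcordanceRecord,
    ConcordanceStatus,
    CopyNumber,
    LocusDefinition,
    Platform,
    Registry,
    StutterObservation,
    StutterType,
)
from .mps_typing import MPSLocusCall

__all__ = [
    "AlleleCensus",
    "TTestResult",
    "census_alleles",
    "compare_locus",
    "compute_balance",
    "students_t",
    "summarize_stutters",
]


def compare_locus(
    ce_call: CELocusCall,
    mps_call: MPSLocusCall,
    locus_def: LocusDefinition,
) -> ConcordanceRecord:
    """Classify one sample x locus CE/MPS comparison.

    Order of precedence: an MPS locus flagged inconclusive for coverage is
    excluded from the comparison; equal sorted length-based allele sets are
    concordant (with duplication/deletion/tri-allelic patterns annotated);
    a set difference fully explained by grey-zone candidates is an apparent
    discordance; anything else is a true discordance.
    """
    if ce_call.sample_id and mps_call.sample_id and ce_call.sample_id != mps_call.sample_id:
        raise ValueError("sample mismatch between CE and MPS calls")
    if ce_call.locus != mps_call.locus:
        raise ValueError("locus mismatch between CE and MPS calls")
    sample_id = ce_call.sample_id or mps_call.sample_id

    ce_alleles = sorted(set(ce_call.alleles))
    mps_alleles = sorted(set(mps_call.alleles))

    def record(status: ConcordanceStatus, notes: str = "") -> ConcordanceRecord:
        return ConcordanceRecord(
            sample_id=sample_id,
            locus=ce_call.locus,
            ce_alleles=ce_alleles,
            mps_alleles=mps_alleles,
            status=status,
            notes=notes,
        )

    if "low_coverage_inc" in mps_call.qc_flags:
        return record(
            ConcordanceStatus.EXCLUDED_INCONCLUSIVE, "MPS coverage inconclusive"
        )

    if ce_alleles == mps_alleles:
        notes = ""
        single = locus_def.copy_number is CopyNumber.SINGLE
        if single and len(ce_alleles) == 2:
            notes = "duplication confirmed"
        elif single and not ce_alleles:
            notes = "deletion confirmed"
        elif len(ce_alleles) >= 3:
            notes = "tri-allelic pattern confirmed"
        return record(ConcordanceStatus.CONCORDANT, notes)

    ce_only = [a for a in ce_alleles if a not in mps_alleles]
    mps_only = [a for a in mps_alleles if a not in ce_alleles]
    grey_lengths = {c.allele.length_allele for c in mps_call.grey_zone_candidates}
    if ce_only and not mps_only and all(a in grey_lengths for a in ce_only):
        missing = ",".join(str(a) for a in ce_only)
        return record(
            ConcordanceStatus.APPARENT_DISCORDANT_GREY_ZONE,
            f"CE allele(s) {missing} present as MPS grey-zone candidate(s)",
        )
    return record(ConcordanceStatus.DISCORDANT)


@dataclass
class AlleleCensus:
    """Unique allele counts per locus: length-based (union of platforms)
    plus MPS-only sequence-based additions."""

    length_based: dict[str, set[AlleleLabel]] = field(default_factory=dict)
    sequence_based: dict[str, set[str]] = field(default_factory=dict)

    @property
    def n_length_based(self) -> int:
        return sum(len(v) for v in self.length_based.values())

    @property
    def n_sequence_based(self) -> int:
        return sum(len(v) for v in self.sequence_based.values())

    def to_frame(self) -> pd.DataFrame:
        loci = sorted(set(self.length_based) | set(self.sequence_based))
        return pd.DataFrame(
            {
                "locus": loci,
                "n_length_based": [
                    len(self.length_based.get(l, set())) for l in loci
                ],
                "n_sequence_based": [
                    len(self.sequence_based.get(l, set())) for l in loci
                ],
            }
        )


def census_alleles(
    ce_calls: Sequence[CELocusCall],
    mps_calls: Sequence[MPSLocusCall],
) -> AlleleCensus:
    """Count unique alleles across the cohort.

    Length-based entries are the union of CE and MPS length calls per
    locus. Sequence-based additions are unique MPS repeat-region sequences
    that deviate from the reference expansion of their length allele
    (iso-alleles, variant homozygotes, and variant sequences in
    heterozygotes), deduplicated per locus.
    """
    census = AlleleCensus()
    for call in ce_calls:
        census.length_based.setdefault(call.locus, set()).update(call.alleles)
    for call in mps_calls:
        bucket = census.length_based.setdefault(call.locus, set())
        for c in call.called:
            bucket.add(c.allele.length_allele)
            if c.allele.is_reference_variant:
                census.sequence_based.setdefault(call.locus, set()).add(
                    c.allele.sequence
                )
    return census


@dataclass
class BalanceExclusion:
    sample_id: str
    locus: str
    platform: Platform
    reason: str


def compute_balance(
    calls: Sequence[Union[CELocusCall, MPSLocusCall]],
    registry: Registry,
) -> tuple[list[BalanceObservation], list[BalanceExclusion]]:
    """Intra-locus balance at multicopy heterozygotes.

    CE balance is minor/major peak height; MPS balance is minimum/maximum
    reads of the typed alleles, each against its platform threshold
    (65% CE, 60% MPS). Genotypes with more than two alleles (the
    tri-allelic pattern) are excluded with a logged reason.
    """
    thresholds = registry.thresholds
    observations: list[BalanceObservation] = []
    exclusions: list[BalanceExclusion] = []
    for call in calls:
        locus_def = registry[call.locus]
        if locus_def.copy_number is not CopyNumber.MULTI:
            continue
        if isinstance(call, CELocusCall):
            platform = Platform.CE
            signals = [(c.allele, c.height_rfu) for c in call.called]
            threshold = thresholds.ilb_threshold_ce
        else:
            platform = Platform.MPS
            signals = [(c.allele.length_allele, float(c.reads)) for c in call.called]
            threshold = thresholds.ilb_threshold_mps
        distinct = {a for a, _ in signals}
        if len(signals) > 2 or len(distinct) > 2:
            exclusions.append(
                BalanceExclusion(
                    call.sample_id,
                    call.locus,
                    platform,
                    f"multi-allelic genotype ({len(distinct)} alleles) excluded "
                    "from balance",
                )
            )
            continue
        if len(signals) != 2 or len(distinct) != 2:
            continue  # homozygous or single-allele: no balance defined
        values = sorted(s for _, s in signals)
        minor, major = values
        ilb = minor / major * 100.0
        observations.append(
            BalanceObservation(
                sample_id=call.sample_id,
                locus=call.locus,
                platform=platform,
                minor_signal=minor,
                major_signal=major,
                ilb_pct=ilb,
                below_threshold=ilb < threshold,
            )
        )
    return observations, exclusions


@dataclass
class TTestResult:
    mean_x: float
    mean_y: float
    t: float
    df: float
    p: float
    ci_low: float
    ci_high: float
    method: str = "student"


def students_t(
    x: Sequence[float], y: Sequence[float], welch: bool = False
) -> TTestResult:
    """Two-sample t-test on percentage samples.

    Default is the classic pooled-variance Student's test with
    ``df = nx + ny - 2`` and a two-sided p; ``welch=True`` switches to the
    unequal-variance form. Returns the 95% confidence interval of the mean
    difference. Degenerate zero-variance groups are handled: identical
    constant groups give t = 0, p = 1.
    """
    x = [float(v) for v in x]
    y = [float(v) for v in y]
    nx, ny = len(x), len(y)
    if nx < 2 or ny < 2:
        raise ValueError("each group needs at least two observations")
    mx = sum(x) / nx
    my = sum(y) / ny
    vx = sum((v - mx) ** 2 for v in x) / (nx - 1)
    vy = sum((v - my) ** 2 for v in y) / (ny - 1)
    diff = mx - my
    if welch:
        se2 = vx / nx + vy / ny
        if se2 > 0:
            df = se2**2 / (
                (vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1)
            )
        else:
            df = float(nx + ny - 2)
        se = math.sqrt(se2)
        method = "welch"
    else:
        sp2 = ((nx - 1) * vx + (ny - 1) * vy) / (nx + ny - 2)
        se = math.sqrt(sp2 * (1.0 / nx + 1.0 / ny))
        df = float(nx + ny - 2)
        method = "student"
    if se == 0.0:
        t = 0.0 if diff == 0 else math.copysign(math.inf, diff)
        p = 1.0 if diff == 0 else 0.0
        ci_low = ci_high = diff
    else:
        t = diff / se
        p = float(2.0 * stats.t.sf(abs(t), df))
        crit = float(stats.t.ppf(0.975, df))
        ci_low, ci_high = diff - crit * se, diff + crit * se
    return TTestResult(mx, my, t, df, p, ci_low, ci_high, method)


def _stutter_filter(
    registry: Registry, locus: str, platform: Platform, stype: StutterType
) -> float | None:
    d = registry[locus]
    if platform is Platform.MPS:
        return d.mps_stutter_filter
    if stype is StutterType.MINUS_ONE_REPEAT:
        return d.ce_minus_stutter_filter
    if stype is StutterType.PLUS_ONE_REPEAT:
        return d.ce_plus_stutter_filter
    return (
        d.ce_minus2nt_stutter_filter
        if d.ce_minus2nt_stutter_filter is not None
        else d.ce_minus_stutter_filter
    )


def summarize_stutters(
    observations: Sequence[StutterObservation],
    registry: Registry,
    denominators: Mapping[tuple[str, Platform, str], int] | None = None,
    welch: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per locus x platform x stutter-type summary plus CE-vs-MPS t-tests.

    Excluded (overlap) observations are omitted from all statistics. The
    detection frequency is the fraction of eligible samples (gated, with a
    called parent at the locus/copy) showing at least one stutter;
    denominators come from the caller because eligibility is a property of
    the calls, not of the observations. Multicopy loci are summarized and
    tested separately per allele copy (a/b).
    """
    kept = [o for o in observations if not o.excluded]
    groups: dict[tuple[str, Platform, str, StutterType], list[StutterObservation]] = {}
    for o in kept:
        copy = o.copy_label or ""
        groups.setdefault((o.locus, o.platform, copy, o.stutter_type), []).append(o)

    rows = []
    for (locus, platform, copy, stype), obs in sorted(
        groups.items(), key=lambda kv: (kv[0][0], kv[0][1].value, kv[0][2], kv[0][3].value)
    ):
        ratios = [o.ratio_pct for o in obs]
        filt = _stutter_filter(registry, locus, platform, stype)
        samples = {o.sample_id for o in obs}
        denom = None
        if denominators is not None:
            denom = denominators.get((locus, platform, copy))
        rows.append(
            {
                "locus": locus,
                "platform": platform.value,
                "copy": copy,
                "stutter_type": stype.value,
                "n": len(ratios),
                "mean_pct": sum(ratios) / len(ratios),
                "min_pct": min(ratios),
                "max_pct": max(ratios),
                "n_above_filter": sum(1 for r in ratios if filt is not None and r > filt),
                "detection_frequency": (
                    len(samples) / denom if denom else float("nan")
                ),
            }
        )
    summary = pd.DataFrame(
        rows,
        columns=[
            "locus",
            "platform",
            "copy",
            "stutter_type",
            "n",
            "mean_pct",
            "min_pct",
            "max_pct",
            "n_above_filter",
            "detection_frequency",
        ],
    )

    # per-locus (per-copy for multicopy) CE vs MPS minus-stutter comparison
    trows = []
    keys = {
        (o.locus, o.copy_label or "")
        for o in kept
        if o.stutter_type is StutterType.MINUS_ONE_REPEAT
    }
    for locus, copy in sorted(keys):
        ce = [
            o.ratio_pct
            for o in kept
            if o.locus == locus
            and (o.copy_label or "") == copy
            and o.platform is Platform.CE
            and o.stutter_type is StutterType.MINUS_ONE_REPEAT
        ]
        mps = [
            o.ratio_pct
            for o in kept
            if o.locus == locus
            and (o.copy_label or "") == copy
            and o.platform is Platform.MPS
            and o.stutter_type is StutterType.MINUS_ONE_REPEAT
        ]
        if len(ce) < 2 or len(mps) < 2:
            continue
        res = students_t(ce, mps, welch=welch)
        trows.append(
            {
                "locus": locus,
                "copy": copy,
                "n_ce": len(ce),
                "n_mps": len(mps),
                "mean_ce": res.mean_x,
                "mean_mps": res.mean_y,
                "t": res.t,
                "df": res.df,
                "p": res.p,
            }
        )
    ttests = pd.DataFrame(
        trows,
        columns=["locus", "copy", "n_ce", "n_mps", "mean_ce", "mean_mps", "t", "df", "p"],
    )
    return summary, ttests
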