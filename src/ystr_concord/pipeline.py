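"""End-to-end analysis engine: tables in, concordance results out.

Thin orchestration over the typing and comparison modules; the CLI and
the numbered analysis scripts both drive this.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence, Union

import pandas as pd

from . import ce_typing, concordance, mps_typing
from .locus_model import (
    BalanceObservation,
    ConcordanceRecord,
    ConcordanceStatus,
    Platform,
    Registry,
    StutterObservation,
    default_registry,
)

__all__ = ["ConcordanceRun", "run_concordance"]

TableLike = Union[str, Path, pd.DataFrame, None]


def _load_table(source: TableLike, parser) -> tuple[list, list]:
    if source is None:
        return [], []
    if isinstance(source, pd.DataFrame):
        buf = io.StringIO()
        source.to_csv(buf, sep="\t", index=False)
        buf.seek(0)
        return parser(buf)
    return parser(source)


@dataclass
class ConcordanceRun:
    registry: Registry
    gates: dict[str, mps_typing.GateResult]
    excluded_samples: list[str]
    ce_calls: dict[tuple[str, str], ce_typing.CELocusCall]
    mps_calls: dict[tuple[str, str], mps_typing.MPSLocusCall]
    records: list[ConcordanceRecord]
    stutter_observations: list[StutterObservation]
    balance_observations: list[BalanceObservation]
    balance_exclusions: list[concordance.BalanceExclusion]
    census: concordance.AlleleCensus
    stutter_summary: pd.DataFrame
    stutter_ttests: pd.DataFrame
    balance_ttests: pd.DataFrame
    ce_rejects: list = field(default_factory=list)
    mps_rejects: list = field(default_factory=list)

    @property
    def concordance_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "sample_id": r.sample_id,
                    "locus": r.locus,
                    "ce_alleles": ",".join(str(a) for a in r.ce_alleles),
                    "mps_alleles": ",".join(str(a) for a in r.mps_alleles),
                    "status": r.status.value,
                    "notes": r.notes,
                }
                for r in self.records
            ],
            columns=["sample_id", "locus", "ce_alleles", "mps_alleles", "status", "notes"],
        )

    @property
    def balance_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "sample_id": b.sample_id,
                    "locus": b.locus,
                    "platform": b.platform.value,
                    "minor_signal": b.minor_signal,
                    "major_signal": b.major_signal,
                    "ilb_pct": b.ilb_pct,
                    "below_threshold": b.below_threshold,
                }
                for b in self.balance_observations
            ],
            columns=[
                "sample_id",
                "locus",
                "platform",
                "minor_signal",
                "major_signal",
                "ilb_pct",
                "below_threshold",
            ],
        )

    def status_counts(self) -> dict[str, int]:
        out: dict[str, int] = {s.value: 0 for s in ConcordanceStatus}
        for r in self.records:
            out[r.status.value] += 1
        return out


def run_concordance(
    ce_table: TableLike,
    mps_table: TableLike,
    registry: Registry | None = None,
    sample_totals: Mapping[str, int] | pd.DataFrame | None = None,
    welch: bool = False,
) -> ConcordanceRun:
    """Run the full CE-vs-MPS comparison.

    ``sample_totals`` supplies per-sample run totals for the 85,000-read
    gate when the MPS table covers only the Y-STR subset of a run; without
    it the gate sums the table itself. Loci present in the data but absent
    from the registry are a hard error.
    """
    registry = registry or default_registry()
    peaks, ce_rejects = _load_table(ce_table, ce_typing.parse_ce_table)
    records_in, mps_rejects = _load_table(mps_table, mps_typing.parse_mps_table)

    unknown = sorted(
        {p.locus for p in peaks if p.locus not in registry}
        | {r.locus for r in records_in if r.locus not in registry}
    )
    if unknown:
        raise KeyError(f"loci present in data but absent from registry: {unknown}")

    if isinstance(sample_totals, pd.DataFrame):
        sample_totals = dict(
            zip(sample_totals["sample_id"].astype(str), sample_totals["total_reads"].astype(int))
        )

    mps_by_sample: dict[str, list[mps_typing.MPSSequenceRecord]] = {}
    for r in records_in:
        mps_by_sample.setdefault(r.sample_id, []).append(r)
    ce_by_sample: dict[str, list[ce_typing.CEPeak]] = {}
    for p in peaks:
        ce_by_sample.setdefault(p.sample_id, []).append(p)

    samples = sorted(set(ce_by_sample) | set(mps_by_sample))
    thresholds = registry.thresholds
    gates: dict[str, mps_typing.GateResult] = {}
    excluded_samples: list[str] = []
    for sid in samples:
        recs = mps_by_sample.get(sid, [])
        total = None if sample_totals is None else int(sample_totals.get(sid, 0))
        if recs or total is not None:
            gate = mps_typing.gate_sample(recs, thresholds, total_reads=total)
            gates[sid] = mps_typing.GateResult(sid, gate.total_reads, gate.passed)
            if not gate.passed:
                excluded_samples.append(sid)

    kept = [s for s in samples if s not in excluded_samples]

    ce_calls: dict[tuple[str, str], ce_typing.CELocusCall] = {}
    mps_calls: dict[tuple[str, str], mps_typing.MPSLocusCall] = {}
    stutters: list[StutterObservation] = []
    for sid in kept:
        ce_groups: dict[str, list[ce_typing.CEPeak]] = {}
        for p in ce_by_sample.get(sid, []):
            ce_groups.setdefault(p.locus, []).append(p)
        mps_groups: dict[str, list[mps_typing.MPSSequenceRecord]] = {}
        for r in mps_by_sample.get(sid, []):
            mps_groups.setdefault(r.locus, []).append(r)
        for locus_def in registry:
            if locus_def.ce_analyzed and (sid in ce_by_sample):
                call = ce_typing.call_ce_locus(
                    ce_groups.get(locus_def.name, []),
                    locus_def,
                    thresholds,
                    sample_id=sid,
                )
                ce_calls[(sid, locus_def.name)] = call
                stutters.extend(ce_typing.collect_ce_stutters(call, locus_def))
            if locus_def.mps_analyzed and (sid in mps_by_sample):
                recs = mps_groups.get(locus_def.name, [])
                mcall = mps_typing.call_mps_locus(
                    recs, locus_def, thresholds, sample_id=sid
                )
                mps_calls[(sid, locus_def.name)] = mcall
                stutters.extend(
                    mps_typing.identify_mps_stutters(recs, mcall, locus_def)
                )

    records: list[ConcordanceRecord] = []
    for sid in kept:
        for locus_def in registry:
            if not (locus_def.ce_analyzed and locus_def.mps_analyzed):
                continue
            key = (sid, locus_def.name)
            if key in ce_calls and key in mps_calls:
                records.append(
                    concordance.compare_locus(
                        ce_calls[key], mps_calls[key], locus_def
                    )
                )

    balance_obs, balance_excl = concordance.compute_balance(
        list(ce_calls.values()) + list(mps_calls.values()), registry
    )
    census = concordance.census_alleles(
        [c for (s, l), c in ce_calls.items() if registry[l].mps_analyzed],
        list(mps_calls.values()),
    )

    denominators: dict[tuple[str, Platform, str], int] = {}
    letters = "abcdef"
    for (sid, locus), call in ce_calls.items():
        n = len(call.called)
        if n == 0:
            continue
        if registry[locus].copy_number.value == "multi":
            for i in range(min(len({c.allele for c in call.called}), 6)):
                denominators[(locus, Platform.CE, letters[i])] = (
                    denominators.get((locus, Platform.CE, letters[i]), 0) + 1
                )
        else:
            denominators[(locus, Platform.CE, "")] = (
                denominators.get((locus, Platform.CE, ""), 0) + 1
            )
    for (sid, locus), call in mps_calls.items():
        if not call.called:
            continue
        if registry[locus].copy_number.value == "multi":
            n_distinct = len({c.allele.length_allele for c in call.called})
            for i in range(min(n_distinct, 6)):
                denominators[(locus, Platform.MPS, letters[i])] = (
                    denominators.get((locus, Platform.MPS, letters[i]), 0) + 1
                )
        else:
            denominators[(locus, Platform.MPS, "")] = (
                denominators.get((locus, Platform.MPS, ""), 0) + 1
            )

    stutter_summary, stutter_ttests = concordance.summarize_stutters(
        stutters, registry, denominators, welch=welch
    )

    brows = []
    for locus in sorted({b.locus for b in balance_obs}):
        ce_vals = [
            b.ilb_pct for b in balance_obs if b.locus == locus and b.platform is Platform.CE
        ]
        mps_vals = [
            b.ilb_pct for b in balance_obs if b.locus == locus and b.platform is Platform.MPS
        ]
        if len(ce_vals) < 2 or len(mps_vals) < 2:
            continue
        res = concordance.students_t(ce_vals, mps_vals, welch=welch)
        brows.append(
            {
                "locus": locus,
                "n_ce": len(ce_vals),
                "n_mps": len(mps_vals),
                "mean_ce": res.mean_x,
                "mean_mps": res.mean_y,
                "t": res.t,
                "df": res.df,
                "p": res.p,
                "ci_low": res.ci_low,
                "ci_high": res.ci_high,
            }
        )
    balance_ttests = pd.DataFrame(
        brows,
        columns=[
            "locus", "n_ce", "n_mps", "mean_ce", "mean_mps",
            "t", "df", "p", "ci_low", "ci_high",
        ],
    )

    return ConcordanceRun(
        registry=registry,
        gates=gates,
        excluded_samples=excluded_samples,
        ce_calls=ce_calls,
        mps_calls=mps_calls,
        records=records,
        stutter_observations=stutters,
        balance_observations=balance_obs,
        balance_exclusions=balance_excl,
        census=census,
        stutter_summary=stutter_summary,
        stutter_ttests=stutter_ttests,
        balance_ttests=balance_ttests,
        ce_rejects=ce_rejects,
        mps_rejects=mps_rejects,
    )
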