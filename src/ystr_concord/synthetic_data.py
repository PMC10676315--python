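"""Paired CE/MPS synthetic profile generator.

Emulates the statistical structure of a 125-male single-source Y-STR
cohort typed on both platforms: locus-specific depth of coverage
(negative-binomial reads, heavy-tailed as real amplicon panels are),
lognormal CE peak heights, per-locus stutter-ratio distributions
(truncated normal), Beta-distributed intra-locus balance at the two
multicopy loci, isometric sequence variants at the designated loci, and
five injectable scenarios: a grey-zone allele dropout at DYS385 a/b (the
primer-binding-site case), a balanced tri-allelic pattern at DYF387S1,
a single-copy duplication and deletion, and a low-coverage inconclusive
locus.

The generator's defaults are the stated world of the study it emulates:
mean depths average ~800 reads with extremes at Y-GATA-H4 (213) and
DYS438 (3,091); stutter means range from ~3% (penta/hexa repeats) to
~30% (the trinucleotide DYS481); run totals average ~93,000 reads so the
85,000-read sample gate passes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .locus_model import (
    AlleleLabel,
    CopyNumber,
    LocusDefinition,
    Registry,
    StutterType,
    default_registry,
)
from .mps_typing import canonical_stutter_sequence, expand_reference

__all__ = [
    "LocusSimParams",
    "SimulatedDataset",
    "SimulationConfig",
    "TrueAllele",
    "TrueProfile",
    "default_simulation_config",
    "render_ce_table",
    "render_mps_table",
    "simulate_dataset",
    "simulate_true_profiles",
    "variant_unit",
]

# scenario -> (sample index, locus) assignments; deterministic so tests and
# reports can name the affected sample x locus
GREY_ZONE_SAMPLE = 0
GREY_ZONE_LOCUS = "DYS385 a/b"
TRIALLELIC_SAMPLE = 1
TRIALLELIC_LOCUS = "DYF387S1"
DUPLICATION_SAMPLE = 2
DUPLICATION_LOCUS = "DYS448"
DELETION_SAMPLE = 3
DELETION_LOCUS = "DYS570"
LOW_COVERAGE_SAMPLE = 4
LOW_COVERAGE_LOCUS = "Y-GATA-H4"


@dataclass
class LocusSimParams:
    mean_doc: float
    minus_stutter_mean_pct: float
    minus_stutter_sd_pct: float
    plus_stutter_mean_pct: float = 0.0
    plus_stutter_sd_pct: float = 0.6
    seq_variant_rate: float = 0.0
    doc_dispersion: float = 8.0  # negative-binomial size parameter
    ce_mean_rfu: float = 6000.0
    ce_rfu_cv: float = 0.30

    def __post_init__(self) -> None:
        if not (0 <= self.seq_variant_rate <= 1):
            raise ValueError("seq_variant_rate must be in [0, 1]")
        if self.mean_doc < 0:
            raise ValueError("mean_doc must be non-negative")


@dataclass
class SimulationConfig:
    n_samples: int = 125
    seed: int = 0
    per_locus: dict[str, LocusSimParams] = field(default_factory=dict)
    ilb_beta_params: tuple[float, float] = (12.0, 2.0)
    offpanel_read_mean: float = 78_000.0
    offpanel_read_sd: float = 3_000.0
    noise_peak_rate: float = 0.10  # chance of one sub-PAT noise peak per locus
    inject_grey_zone_dropout: bool = True
    inject_triallelic: bool = True
    inject_duplication: bool = True
    inject_deletion: bool = True
    inject_low_coverage_locus: bool = True

    def clean(self) -> "SimulationConfig":
        """Copy with every scenario injection switched off."""
        return replace(
            self,
            per_locus=dict(self.per_locus),
            inject_grey_zone_dropout=False,
            inject_triallelic=False,
            inject_duplication=False,
            inject_deletion=False,
            inject_low_coverage_locus=False,
        )


# mean DoC, minus stutter mean/sd, plus stutter mean, sequence-variant rate.
# Depths average ~800 across the panel with the stated extremes; variants
# are confined to the eight loci where sequence variation was seen.
_LOCUS_DEFAULTS: dict[str, tuple[float, float, float, float, float]] = {
    "DYS19": (600, 9, 2.0, 0.0, 0.10),
    "DYS385 a/b": (280, 12, 1.5, 0.0, 0.0),
    "DYS389I": (800, 10, 2.0, 2.5, 0.0),
    "DYS389II": (700, 13, 2.0, 0.0, 0.15),
    "DYS390": (900, 11, 2.0, 2.5, 0.0),
    "DYS391": (850, 8, 1.5, 2.5, 0.0),
    "DYS392": (300, 12, 2.0, 0.0, 0.0),
    "DYS437": (950, 7, 1.5, 2.5, 0.0),
    "DYS438": (3091, 3, 0.8, 2.5, 0.08),
    "DYS439": (800, 12, 2.0, 2.5, 0.0),
    "DYS448": (500, 3, 0.8, 2.5, 0.10),
    "DYS460": (650, 10, 2.0, 0.0, 0.0),
    "DYS481": (750, 30, 3.0, 2.5, 0.10),
    "DYS533": (700, 9, 2.0, 0.0, 0.0),
    "DYS570": (1000, 11, 2.0, 2.5, 0.08),
    "DYS576": (1100, 12, 2.0, 2.5, 0.0),
    "DYS635": (900, 10, 2.0, 0.0, 0.10),
    "DYF387S1": (300, 13, 1.5, 0.0, 0.15),
    "Y-GATA-H4": (213, 8, 2.0, 0.0, 0.0),
}


def default_simulation_config(
    registry: Registry | None = None,
    n_samples: int = 125,
    seed: int = 0,
    **overrides,
) -> SimulationConfig:
    registry = registry or default_registry()
    per_locus: dict[str, LocusSimParams] = {}
    for d in registry:
        doc, sm, ss, pm, vr = _LOCUS_DEFAULTS.get(d.name, (700, 10, 2.0, 0.0, 0.0))
        per_locus[d.name] = LocusSimParams(
            mean_doc=doc,
            minus_stutter_mean_pct=sm,
            minus_stutter_sd_pct=ss,
            plus_stutter_mean_pct=pm,
            seq_variant_rate=vr,
        )
    return SimulationConfig(
        n_samples=n_samples, seed=seed, per_locus=per_locus, **overrides
    )


@dataclass(frozen=True)
class TrueAllele:
    label: AlleleLabel
    sequence: str
    is_variant: bool


@dataclass
class TrueProfile:
    sample_id: str
    alleles: dict[str, list[TrueAllele]]
    annotations: dict[str, str] = field(default_factory=dict)


_ALT_BASE = {"A": "G", "G": "A", "C": "T", "T": "C"}


def variant_unit(motif: str) -> str:
    """Alternate repeat unit: the canonical motif with its second base swapped."""
    i = 1 if len(motif) > 1 else 0
    return motif[:i] + _ALT_BASE[motif[i]] + motif[i + 1 :]


def _variant_sequence(locus_def: LocusDefinition, allele: AlleleLabel) -> str:
    """Isometric variant: one unit of the primary run swapped for the
    alternate motif — same total length, different string. The substituted
    position is a fixed function of (locus, allele) so variants recur as
    haplotypes across carriers, as real repeat-region variants do."""
    base = expand_reference(locus_def, allele)
    unit = locus_def.repeat_unit_length
    motif = locus_def.motif_structure[locus_def.primary_expandable_block].motif
    n_units = len(base) // unit
    positions = [
        i for i in range(n_units) if base[i * unit : (i + 1) * unit] == motif
    ]
    if not positions:
        return base
    pos = positions[len(positions) // 2]
    alt = variant_unit(motif)
    return base[: pos * unit] + alt + base[(pos + 1) * unit :]


def _draw_allele(
    locus_def: LocusDefinition, rng: np.random.Generator
) -> AlleleLabel:
    lo, hi = locus_def.allele_range or (
        locus_def.reference_allele().repeats - 3,
        locus_def.reference_allele().repeats + 3,
    )
    return AlleleLabel(int(rng.integers(lo, hi + 1)))


def _make_true_allele(
    locus_def: LocusDefinition,
    label: AlleleLabel,
    params: LocusSimParams,
    rng: np.random.Generator,
) -> TrueAllele:
    if params.seq_variant_rate > 0 and rng.random() < params.seq_variant_rate:
        seq = _variant_sequence(locus_def, label)
        return TrueAllele(label, seq, seq != expand_reference(locus_def, label))
    return TrueAllele(label, expand_reference(locus_def, label), False)


def simulate_true_profiles(
    config: SimulationConfig, registry: Registry | None = None
) -> list[TrueProfile]:
    """Draw ground-truth genotypes (deterministic given config.seed)."""
    registry = registry or default_registry()
    for name in config.per_locus:
        if name not in registry:
            raise KeyError(f"simulation config names unknown locus {name!r}")
    rng = np.random.default_rng([config.seed, 101])
    profiles: list[TrueProfile] = []
    for i in range(config.n_samples):
        sample_id = f"S{i + 1:03d}"
        alleles: dict[str, list[TrueAllele]] = {}
        annotations: dict[str, str] = {}
        for locus_def in registry:
            params = config.per_locus.get(locus_def.name)
            if params is None:
                continue
            n_copies = 2 if locus_def.copy_number is CopyNumber.MULTI else 1
            labels = sorted(_draw_allele(locus_def, rng) for _ in range(n_copies))
            alleles[locus_def.name] = [
                _make_true_allele(locus_def, lab, params, rng) for lab in labels
            ]
        # scenario injections overwrite the draws at designated sample x locus
        if config.inject_grey_zone_dropout and i == GREY_ZONE_SAMPLE:
            d = registry[GREY_ZONE_LOCUS]
            alleles[GREY_ZONE_LOCUS] = [
                TrueAllele(AlleleLabel(14), expand_reference(d, 14), False),
                TrueAllele(AlleleLabel(19), expand_reference(d, 19), False),
            ]
            annotations[GREY_ZONE_LOCUS] = "grey_zone_dropout"
        if config.inject_triallelic and i == TRIALLELIC_SAMPLE:
            d = registry[TRIALLELIC_LOCUS]
            alleles[TRIALLELIC_LOCUS] = [
                TrueAllele(AlleleLabel(k), expand_reference(d, k), False)
                for k in (37, 38, 39)
            ]
            annotations[TRIALLELIC_LOCUS] = "triallelic"
        if config.inject_duplication and i == DUPLICATION_SAMPLE:
            d = registry[DUPLICATION_LOCUS]
            alleles[DUPLICATION_LOCUS] = [
                TrueAllele(AlleleLabel(19), expand_reference(d, 19), False),
                TrueAllele(AlleleLabel(22), expand_reference(d, 22), False),
            ]
            annotations[DUPLICATION_LOCUS] = "duplication"
        if config.inject_deletion and i == DELETION_SAMPLE:
            alleles[DELETION_LOCUS] = []
            annotations[DELETION_LOCUS] = "deletion"
        if config.inject_low_coverage_locus and i == LOW_COVERAGE_SAMPLE:
            annotations[LOW_COVERAGE_LOCUS] = "low_coverage"
        profiles.append(TrueProfile(sample_id, alleles, annotations))
    return profiles


def _draw_ratio(mean: float, sd: float, rng: np.random.Generator) -> float:
    """Normal stutter-ratio draw truncated at zero (rejection sampling)."""
    for _ in range(100):
        x = rng.normal(mean, sd)
        if x > 0:
            return x
    return max(mean, 0.1)


def _lognormal(mean: float, cv: float, rng: np.random.Generator) -> float:
    sigma = np.sqrt(np.log(1.0 + cv * cv))
    mu = np.log(mean) - sigma * sigma / 2.0
    return float(rng.lognormal(mu, sigma))


def _negbin(mean: float, k: float, rng: np.random.Generator) -> int:
    if mean <= 0:
        return 0
    p = k / (k + mean)
    return int(rng.negative_binomial(k, p))


def render_ce_table(
    profiles: Sequence[TrueProfile],
    config: SimulationConfig,
    registry: Registry | None = None,
) -> pd.DataFrame:
    """Render a GeneMapper-style CE peak table for the true profiles.

    Each true allele yields a parent peak (lognormal height, multicopy
    minor alleles scaled by a Beta balance draw), a minus-stutter peak one
    repeat below, and optionally a plus-stutter peak; signals landing on
    the same allele position add up, as co-migrating fragments do in an
    electropherogram. Noise peaks stay strictly below the PAT.
    """
    registry = registry or default_registry()
    rng = np.random.default_rng([config.seed, 202])
    pat = registry.thresholds.pat_rfu
    a, b = config.ilb_beta_params
    rows: list[dict] = []
    for profile in profiles:
        for locus_def in registry:
            if not locus_def.ce_analyzed or locus_def.name not in profile.alleles:
                continue
            params = config.per_locus[locus_def.name]
            truth = profile.alleles[locus_def.name]
            unit = locus_def.repeat_unit_length
            heights: dict[AlleleLabel, float] = {}

            def add(lab: AlleleLabel, h: float) -> None:
                heights[lab] = heights.get(lab, 0.0) + h

            parent_heights: list[tuple[AlleleLabel, float]] = []
            balanced = (
                profile.annotations.get(locus_def.name) == "triallelic"
            )
            for rank, ta in enumerate(truth):
                if rank == 0:
                    h = _lognormal(params.ce_mean_rfu, params.ce_rfu_cv, rng)
                    anchor = h
                elif balanced:
                    h = anchor * rng.uniform(0.88, 1.0)
                else:
                    h = anchor * rng.beta(a, b)
                parent_heights.append((ta.label, h))
                add(ta.label, h)
            for lab, h in parent_heights:
                minus = _draw_ratio(
                    params.minus_stutter_mean_pct, params.minus_stutter_sd_pct, rng
                )
                if lab.repeats >= 1:
                    add(lab.shift_repeats(-1), h * minus / 100.0)
                if params.plus_stutter_mean_pct > 0:
                    plus = _draw_ratio(
                        params.plus_stutter_mean_pct, params.plus_stutter_sd_pct, rng
                    )
                    add(lab.shift_repeats(+1), h * plus / 100.0)
            if truth and rng.random() < config.noise_peak_rate:
                lo, hi = locus_def.allele_range or (5, 30)
                noise_lab = AlleleLabel(int(rng.integers(lo - 2, hi + 1)))
                if noise_lab not in heights:
                    add(noise_lab, float(rng.uniform(20.0, pat - 5.0)))
            for lab in sorted(heights):
                rows.append(
                    {
                        "sample_id": profile.sample_id,
                        "locus": locus_def.name,
                        "allele": str(lab),
                        "size_bp": 100 + lab.total_nt(unit),
                        "height_rfu": round(heights[lab], 4),
                        "dye": locus_def.dye,
                    }
                )
    return pd.DataFrame(rows, columns=["sample_id", "locus", "allele", "size_bp", "height_rfu", "dye"])


def render_mps_table(
    profiles: Sequence[TrueProfile],
    config: SimulationConfig,
    registry: Registry | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Render a UAS-style per-locus sequence-read table plus run totals.

    Returns ``(records, sample_totals)``. Parent reads are
    negative-binomial; multicopy minor alleles scale by the Beta balance
    draw; stutter sequences are the parent sequence with one repeat of the
    expandable motif removed/added. Reads of identical sequences merge.
    The grey-zone scenario forces the dropout allele's reads between the
    locus AT and IT (19 reads, the reported figure); the low-coverage
    scenario drives a designated locus below callable depth. Run totals
    add an off-panel read count so the 85,000-read gate behaves as on a
    full sequencing run.
    """
    registry = registry or default_registry()
    rng = np.random.default_rng([config.seed, 303])
    a, b = config.ilb_beta_params
    rows: list[dict] = []
    totals: list[dict] = []
    for profile in profiles:
        ystr_total = 0
        for locus_def in registry:
            if locus_def.name not in profile.alleles:
                continue
            params = config.per_locus[locus_def.name]
            if params.mean_doc <= 0:
                continue  # total locus dropout: no records at all
            truth = profile.alleles[locus_def.name]
            annotation = profile.annotations.get(locus_def.name)
            reads_by_seq: dict[str, int] = {}
            true_seqs: list[tuple[str, int]] = []

            def add(seq: str, n: int) -> None:
                if n >= 1 and seq:
                    reads_by_seq[seq] = reads_by_seq.get(seq, 0) + n

            parent_reads: list[tuple[TrueAllele, int]] = []
            balanced = annotation == "triallelic"
            for rank, ta in enumerate(truth):
                if rank == 0:
                    n = max(_negbin(params.mean_doc, params.doc_dispersion, rng), 1)
                    anchor = n
                elif balanced:
                    n = max(int(round(anchor * rng.uniform(0.88, 1.0))), 1)
                else:
                    n = max(int(round(anchor * rng.beta(a, b))), 1)
                parent_reads.append((ta, n))
            if annotation == "grey_zone_dropout":
                # primer-binding-site mutation starves the larger allele:
                # its reads land between the AT (10) and the IT (30)
                parent_reads = [
                    (ta, 19 if ta.label == max(t.label for t in truth) else n)
                    for ta, n in parent_reads
                ]
            if annotation == "low_coverage":
                parent_reads = [
                    (ta, int(rng.integers(3, 9))) for ta, _n in parent_reads
                ]
            for ta, n in parent_reads:
                add(ta.sequence, n)
                true_seqs.append((ta.sequence, n))
                minus = _draw_ratio(
                    params.minus_stutter_mean_pct, params.minus_stutter_sd_pct, rng
                )
                try:
                    add(
                        canonical_stutter_sequence(
                            ta.sequence, locus_def, StutterType.MINUS_ONE_REPEAT
                        ),
                        int(round(n * minus / 100.0)),
                    )
                except ValueError:
                    pass
                if params.plus_stutter_mean_pct > 0:
                    plus = _draw_ratio(
                        params.plus_stutter_mean_pct, params.plus_stutter_sd_pct, rng
                    )
                    add(
                        canonical_stutter_sequence(
                            ta.sequence, locus_def, StutterType.PLUS_ONE_REPEAT
                        ),
                        int(round(n * plus / 100.0)),
                    )
            if not reads_by_seq:
                continue
            top_true = max(true_seqs, key=lambda t: reads_by_seq[t[0]], default=None)
            for seq in sorted(reads_by_seq):
                rows.append(
                    {
                        "sample_id": profile.sample_id,
                        "locus": locus_def.name,
                        "sequence": seq,
                        "reads": reads_by_seq[seq],
                        "typed_flag": "YES"
                        if top_true is not None and seq == top_true[0]
                        else "NO",
                    }
                )
                ystr_total += reads_by_seq[seq]
        offpanel = max(
            int(round(rng.normal(config.offpanel_read_mean, config.offpanel_read_sd))),
            0,
        )
        totals.append(
            {
                "sample_id": profile.sample_id,
                "ystr_reads": ystr_total,
                "total_reads": ystr_total + offpanel,
            }
        )
    records = pd.DataFrame(
        rows, columns=["sample_id", "locus", "sequence", "reads", "typed_flag"]
    )
    return records, pd.DataFrame(
        totals, columns=["sample_id", "ystr_reads", "total_reads"]
    )


@dataclass
class SimulatedDataset:
    profiles: list[TrueProfile]
    ce_table: pd.DataFrame
    mps_table: pd.DataFrame
    sample_totals: pd.DataFrame


def simulate_dataset(
    config: SimulationConfig, registry: Registry | None = None
) -> SimulatedDataset:
    registry = registry or default_registry()
    profiles = simulate_true_profiles(config, registry)
    ce = render_ce_table(profiles, config, registry)
    mps, totals = render_mps_table(profiles, config, registry)
    return SimulatedDataset(profiles, ce, mps, totals)
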