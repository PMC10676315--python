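"""Domain types and locus-definition registry for Y-STR concordance analysis.

A *locus definition* describes one Y-STR marker: its repeat-region
architecture (ordered motif blocks), copy number (single-copy vs multicopy
markers such as DYS385 a/b), and the platform-specific thresholds and
stutter filters used when calling alleles from capillary-electrophoresis
(CE) peak tables or massively-parallel-sequencing (MPS) read tables.

Allele labels follow forensic convention: the integer number of counted
repeat units, with microvariants written as ``repeats.partial`` (e.g.
``"13.2"`` = 13 full repeats plus 2 nucleotides).
"""

from __future__ import annotations

import enum
import io
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator, Union

import yaml

__all__ = [
    "AlleleLabel",
    "BalanceObservation",
    "ConcordanceRecord",
    "ConcordanceStatus",
    "ConfigError",
    "CopyNumber",
    "ExclusionReason",
    "LocusDefinition",
    "MotifBlock",
    "Platform",
    "Registry",
    "RegistryValidationError",
    "StutterObservation",
    "StutterType",
    "ThresholdConfig",
    "ValidationIssue",
    "default_registry",
    "load_locus_registry",
    "validate_registry",
    "write_registry",
]


class ConfigError(ValueError):
    """Raised when a registry config cannot be parsed or is inconsistent."""


class RegistryValidationError(ConfigError):
    """Raised when a loaded registry violates a hard invariant."""


class CopyNumber(str, enum.Enum):
    SINGLE = "single"
    MULTI = "multi"


class Platform(str, enum.Enum):
    CE = "CE"
    MPS = "MPS"


class StutterType(str, enum.Enum):
    MINUS_ONE_REPEAT = "minus_one_repeat"
    PLUS_ONE_REPEAT = "plus_one_repeat"
    MINUS_2NT = "minus_2nt"


class ExclusionReason(str, enum.Enum):
    NONE = "none"
    OVERLAPS_SMALLER_ALLELE = "overlaps_smaller_allele"
    OVERLAPS_LARGER_ALLELE = "overlaps_larger_allele"


class ConcordanceStatus(str, enum.Enum):
    CONCORDANT = "concordant"
    DISCORDANT = "discordant"
    APPARENT_DISCORDANT_GREY_ZONE = "apparent_discordant_grey_zone"
    EXCLUDED_INCONCLUSIVE = "excluded_inconclusive"


@dataclass(frozen=True, order=True)
class AlleleLabel:
    """Length-based allele identity: full repeats plus residual nucleotides."""

    repeats: int
    partial_nt: int = 0

    def __post_init__(self) -> None:
        if self.repeats < 0 or self.partial_nt < 0:
            raise ValueError(f"negative allele components: {self!r}")

    @classmethod
    def parse(cls, text: Union[str, int, float]) -> "AlleleLabel":
        s = str(text).strip()
        if "." in s:
            whole, frac = s.split(".", 1)
            return cls(int(whole), int(frac))
        return cls(int(s))

    def total_nt(self, repeat_unit_length: int) -> int:
        return self.repeats * repeat_unit_length + self.partial_nt

    @classmethod
    def from_total_nt(cls, total_nt: int, repeat_unit_length: int) -> "AlleleLabel":
        if total_nt < 0:
            raise ValueError("negative sequence length")
        return cls(total_nt // repeat_unit_length, total_nt % repeat_unit_length)

    def shift_repeats(self, delta: int) -> "AlleleLabel":
        return AlleleLabel(self.repeats + delta, self.partial_nt)

    def shift_nt(self, delta_nt: int, repeat_unit_length: int) -> "AlleleLabel":
        return AlleleLabel.from_total_nt(
            self.total_nt(repeat_unit_length) + delta_nt, repeat_unit_length
        )

    def __str__(self) -> str:
        if self.partial_nt:
            return f"{self.repeats}.{self.partial_nt}"
        return str(self.repeats)


@dataclass(frozen=True)
class MotifBlock:
    """One block of the reference repeat-region architecture."""

    motif: str
    expandable: bool
    ref_count: int

    def __post_init__(self) -> None:
        if not self.motif or set(self.motif) - set("ACGT"):
            raise ValueError(f"motif must be over ACGT: {self.motif!r}")
        if self.ref_count < 0:
            raise ValueError("negative reference repeat count")


@dataclass
class LocusDefinition:
    name: str
    copy_number: CopyNumber
    repeat_unit_length: int
    motif_structure: list[MotifBlock]
    counted_blocks: list[int]
    ce_minus_stutter_filter: float
    mps_stutter_filter: float
    at_pct: float
    it_pct: float
    ce_plus_stutter_filter: float | None = None
    ce_minus2nt_stutter_filter: float | None = None
    ce_analyzed: bool = True
    mps_analyzed: bool = True
    allele_range: tuple[int, int] | None = None
    dye: str = "B"

    @property
    def max_expected_alleles(self) -> int:
        return 2 if self.copy_number is CopyNumber.MULTI else 1

    @property
    def primary_expandable_block(self) -> int:
        """Index of the block that absorbs repeat-count variation on expansion.

        Convention: the last expandable *counted* block.
        """
        candidates = [
            i
            for i in self.counted_blocks
            if self.motif_structure[i].expandable
        ]
        if not candidates:
            raise RegistryValidationError(
                f"{self.name}: no expandable counted block"
            )
        return candidates[-1]

    def reference_allele(self) -> AlleleLabel:
        return AlleleLabel(
            sum(self.motif_structure[i].ref_count for i in self.counted_blocks)
        )

    def issues(self) -> list["ValidationIssue"]:
        out: list[ValidationIssue] = []

        def err(msg: str) -> None:
            out.append(ValidationIssue(self.name, "error", msg))

        def warn(msg: str) -> None:
            out.append(ValidationIssue(self.name, "warning", msg))

        if self.repeat_unit_length not in (3, 4, 5, 6):
            err(f"repeat_unit_length {self.repeat_unit_length} not in 3-6")
        if not (0 < self.at_pct < self.it_pct < 100):
            err(f"thresholds must satisfy 0 < AT ({self.at_pct}) < IT ({self.it_pct}) < 100")
        if not self.motif_structure:
            err("empty motif structure")
        else:
            if not any(b.expandable for b in self.motif_structure):
                err("no expandable block")
            for i in self.counted_blocks:
                if not (0 <= i < len(self.motif_structure)):
                    err(f"counted block index {i} out of range")
            for b in self.motif_structure:
                if len(b.motif) != self.repeat_unit_length:
                    warn(
                        f"block motif {b.motif!r} length differs from "
                        f"repeat_unit_length {self.repeat_unit_length}"
                    )
        if not (15 <= self.mps_stutter_filter <= 50):
            warn(
                f"mps_stutter_filter {self.mps_stutter_filter} outside the "
                "15-50% default range"
            )
        if self.ce_minus_stutter_filter <= 0:
            err("ce_minus_stutter_filter must be positive")
        return out


@dataclass
class ThresholdConfig:
    """Global platform thresholds (defaults follow vendor guidance)."""

    pat_rfu: float = 175.0
    ce_het_rfu: float = 100.0
    ce_hom_rfu: float = 200.0
    mps_sample_read_gate: int = 85_000
    mps_recalc_basis_reads: int = 650
    ilb_threshold_ce: float = 65.0
    ilb_threshold_mps: float = 60.0
    recalc_basis: str = "floor650"  # or "hardfloor"

    def issues(self) -> list["ValidationIssue"]:
        out: list[ValidationIssue] = []
        for name in (
            "pat_rfu",
            "ce_het_rfu",
            "ce_hom_rfu",
            "mps_sample_read_gate",
            "mps_recalc_basis_reads",
            "ilb_threshold_ce",
            "ilb_threshold_mps",
        ):
            if getattr(self, name) <= 0:
                out.append(ValidationIssue("<defaults>", "error", f"{name} must be positive"))
        if self.ce_het_rfu > self.ce_hom_rfu:
            out.append(
                ValidationIssue(
                    "<defaults>", "error", "ce_het_rfu must not exceed ce_hom_rfu"
                )
            )
        if self.recalc_basis not in ("floor650", "hardfloor"):
            out.append(
                ValidationIssue(
                    "<defaults>", "error", f"unknown recalc_basis {self.recalc_basis!r}"
                )
            )
        return out


@dataclass(frozen=True)
class ValidationIssue:
    locus: str
    level: str  # "error" | "warning"
    message: str


@dataclass
class StutterObservation:
    sample_id: str
    locus: str
    platform: Platform
    parent_allele: AlleleLabel
    stutter_type: StutterType
    ratio_pct: float
    excluded: bool = False
    exclusion_reason: ExclusionReason = ExclusionReason.NONE
    copy_label: str | None = None  # "a"/"b" for multicopy parents
    notes: str = ""

    def __post_init__(self) -> None:
        if self.ratio_pct <= 0:
            raise ValueError("ratio_pct must be positive")
        if self.excluded != (self.exclusion_reason is not ExclusionReason.NONE):
            raise ValueError("excluded flag inconsistent with exclusion_reason")


@dataclass
class BalanceObservation:
    sample_id: str
    locus: str
    platform: Platform
    minor_signal: float
    major_signal: float
    ilb_pct: float
    below_threshold: bool

    def __post_init__(self) -> None:
        if self.minor_signal > self.major_signal:
            raise ValueError("minor_signal exceeds major_signal")
        if not (0 < self.ilb_pct <= 100):
            raise ValueError("ilb_pct out of (0, 100]")


@dataclass
class ConcordanceRecord:
    sample_id: str
    locus: str
    ce_alleles: list[AlleleLabel]
    mps_alleles: list[AlleleLabel]
    status: ConcordanceStatus
    notes: str = ""


class Registry:
    """Ordered collection of locus definitions plus global thresholds."""

    def __init__(
        self, loci: Iterable[LocusDefinition], thresholds: ThresholdConfig
    ) -> None:
        self._loci: dict[str, LocusDefinition] = {}
        for locus in loci:
            if locus.name in self._loci:
                raise ConfigError(f"duplicate locus name: {locus.name}")
            self._loci[locus.name] = locus
        self.thresholds = thresholds

    def __iter__(self) -> Iterator[LocusDefinition]:
        return iter(self._loci.values())

    def __len__(self) -> int:
        return len(self._loci)

    def __contains__(self, name: str) -> bool:
        return name in self._loci

    def __getitem__(self, name: str) -> LocusDefinition:
        try:
            return self._loci[name]
        except KeyError:
            raise KeyError(f"locus not in registry: {name!r}") from None

    @property
    def locus_names(self) -> list[str]:
        return list(self._loci)

    def analyzed(self, platform: Platform) -> list[LocusDefinition]:
        flag = "ce_analyzed" if platform is Platform.CE else "mps_analyzed"
        return [d for d in self if getattr(d, flag)]


_THRESHOLD_KEYS = {
    "pat_rfu",
    "ce_het_rfu",
    "ce_hom_rfu",
    "mps_sample_read_gate",
    "mps_recalc_basis_reads",
    "ilb_threshold_ce",
    "ilb_threshold_mps",
    "recalc_basis",
}


def _parse_locus(name: str, raw: dict, defaults: dict) -> LocusDefinition:
    blocks = [
        MotifBlock(str(m).upper(), bool(e), int(c))
        for m, e, c in raw["motif_structure"]
    ]
    counted = raw.get("counted_blocks")
    if counted is None:
        counted = list(range(len(blocks)))
    rng = raw.get("allele_range")
    try:
        return LocusDefinition(
            name=name,
            copy_number=CopyNumber(raw.get("copy_number", "single")),
            repeat_unit_length=int(raw["repeat_unit_length"]),
            motif_structure=blocks,
            counted_blocks=[int(i) for i in counted],
            ce_minus_stutter_filter=float(raw["ce_minus_stutter_filter"]),
            ce_plus_stutter_filter=(
                None
                if raw.get("ce_plus_stutter_filter") is None
                else float(raw["ce_plus_stutter_filter"])
            ),
            ce_minus2nt_stutter_filter=(
                None
                if raw.get("ce_minus2nt_stutter_filter") is None
                else float(raw["ce_minus2nt_stutter_filter"])
            ),
            mps_stutter_filter=float(raw["mps_stutter_filter"]),
            at_pct=float(raw.get("at_pct", defaults.get("at_pct", 1.5))),
            it_pct=float(raw.get("it_pct", defaults.get("it_pct", 4.5))),
            ce_analyzed=bool(raw.get("ce_analyzed", True)),
            mps_analyzed=bool(raw.get("mps_analyzed", True)),
            allele_range=None if rng is None else (int(rng[0]), int(rng[1])),
            dye=str(raw.get("dye", "B")),
        )
    except (KeyError, TypeError, ValueError) as exc:
        raise ConfigError(f"locus {name!r}: {exc}") from exc


def load_locus_registry(source: Union[str, Path, io.TextIOBase]) -> Registry:
    """Load a locus registry from YAML text, a path, or an open stream.

    The file holds a global ``defaults:`` section (ThresholdConfig fields and
    default AT/IT percentages) and a ``loci:`` mapping with one section per
    locus. Per-locus keys override the global defaults.
    """
    if isinstance(source, io.TextIOBase):
        text = source.read()
    elif isinstance(source, Path) or (
        isinstance(source, str) and "\n" not in source and source.endswith((".yaml", ".yml"))
    ):
        text = Path(source).read_text(encoding="utf-8")
    else:
        text = str(source)
    try:
        doc = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise ConfigError(f"registry config does not parse: {exc}") from exc
    if not isinstance(doc, dict) or "loci" not in doc:
        raise ConfigError("registry config must contain a 'loci' mapping")

    defaults = dict(doc.get("defaults") or {})
    thr_kwargs = {k: v for k, v in defaults.items() if k in _THRESHOLD_KEYS}
    thresholds = ThresholdConfig(**thr_kwargs)

    loci = [_parse_locus(name, raw or {}, defaults) for name, raw in doc["loci"].items()]
    registry = Registry(loci, thresholds)

    errors = [i for i in validate_registry(registry) if i.level == "error"]
    if errors:
        detail = "; ".join(f"{i.locus}: {i.message}" for i in errors)
        raise RegistryValidationError(f"invalid registry: {detail}")
    return registry


def validate_registry(registry: Registry) -> list[ValidationIssue]:
    """Report every invariant violation; empty for the shipped defaults."""
    issues: list[ValidationIssue] = []
    if len(registry) == 0:
        issues.append(ValidationIssue("<registry>", "error", "no loci defined"))
    issues.extend(registry.thresholds.issues())
    for locus in registry:
        issues.extend(locus.issues())
    return issues


def write_registry(registry: Registry, path: Union[str, Path, None] = None) -> str:
    """Serialize a registry back to YAML (round-trips through load)."""
    thr = registry.thresholds
    doc: dict = {
        "defaults": {
            "pat_rfu": thr.pat_rfu,
            "ce_het_rfu": thr.ce_het_rfu,
            "ce_hom_rfu": thr.ce_hom_rfu,
            "mps_sample_read_gate": thr.mps_sample_read_gate,
            "mps_recalc_basis_reads": thr.mps_recalc_basis_reads,
            "ilb_threshold_ce": thr.ilb_threshold_ce,
            "ilb_threshold_mps": thr.ilb_threshold_mps,
            "recalc_basis": thr.recalc_basis,
        },
        "loci": {},
    }
    for d in registry:
        entry: dict = {
            "copy_number": d.copy_number.value,
            "repeat_unit_length": d.repeat_unit_length,
            "motif_structure": [[b.motif, b.expandable, b.ref_count] for b in d.motif_structure],
            "counted_blocks": list(d.counted_blocks),
            "ce_minus_stutter_filter": d.ce_minus_stutter_filter,
            "mps_stutter_filter": d.mps_stutter_filter,
            "at_pct": d.at_pct,
            "it_pct": d.it_pct,
            "ce_analyzed": d.ce_analyzed,
            "mps_analyzed": d.mps_analyzed,
            "dye": d.dye,
        }
        if d.ce_plus_stutter_filter is not None:
            entry["ce_plus_stutter_filter"] = d.ce_plus_stutter_filter
        if d.ce_minus2nt_stutter_filter is not None:
            entry["ce_minus2nt_stutter_filter"] = d.ce_minus2nt_stutter_filter
        if d.allele_range is not None:
            entry["allele_range"] = list(d.allele_range)
        doc["loci"][d.name] = entry
    text = yaml.safe_dump(doc, sort_keys=False)
    if path is not None:
        Path(path).write_text(text, encoding="utf-8")
    return text


def default_registry() -> Registry:
    """The shipped 19-locus registry (18 analyzed on MPS; DYS392 excluded)."""
    data = resources.files("ystr_concord").joinpath("data/default_registry.yaml")
    return load_locus_registry(data.read_text(encoding="utf-8"))
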