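import pytest

from ystr_concord.locus_model import (
    CopyNumber,
    LocusDefinition,
    MotifBlock,
    Registry,
    ThresholdConfig,
    default_registry,
)


@pytest.fixture(scope="session")
def registry() -> Registry:
    return default_registry()


@pytest.fixture()
def thresholds() -> ThresholdConfig:
    return ThresholdConfig()


def _toy(name: str, copy_number: CopyNumber) -> LocusDefinition:
    return LocusDefinition(
        name=name,
        copy_number=copy_number,
        repeat_unit_length=4,
        motif_structure=[MotifBlock("TCTA", True, 10)],
        counted_blocks=[0],
        ce_minus_stutter_filter=15.0,
        ce_plus_stutter_filter=8.0,
        mps_stutter_filter=20.0,
        at_pct=1.5,
        it_pct=4.5,
        allele_range=(5, 15),
    )


@pytest.fixture()
def toy_locus() -> LocusDefinition:
    """Single-copy [TCTA]n toy marker."""
    return _toy("TOY", CopyNumber.SINGLE)


@pytest.fixture()
def toy_multi() -> LocusDefinition:
    """Multicopy [TCTA]n toy marker (DYS385-like)."""
    return _toy("TOYM", CopyNumber.MULTI)


@pytest.fixture()
def toy_compound() -> LocusDefinition:
    """Two expandable blocks plus a fixed uncounted tail block."""
    return LocusDefinition(
        name="TOYC",
        copy_number=CopyNumber.SINGLE,
        repeat_unit_length=4,
        motif_structure=[
            MotifBlock("TCTG", True, 3),
            MotifBlock("TCTA", True, 8),
            MotifBlock("GGGG", False, 1),
        ],
        counted_blocks=[0, 1],
        ce_minus_stutter_filter=15.0,
        mps_stutter_filter=20.0,
        at_pct=1.5,
        it_pct=4.5,
        allele_range=(6, 16),
    )
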