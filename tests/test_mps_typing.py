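"""MPS gating, threshold recalculation, bracket nomenclature, calling,
iso-allele detection and sequence-exact stutter identification."""

import io

import pytest
from hypothesis import HealthCheck, given, settings
from hypothesis import strategies as st

from ystr_concord.locus_model import (
    AlleleLabel,
    ExclusionReason,
    StutterType,
    ThresholdConfig,
)
from ystr_concord.mps_typing import (
    BracketParseError,
    MPSSequenceRecord,
    bracket_sequence,
    call_mps_locus,
    canonical_stutter_sequence,
    detect_iso_alleles,
    expand_bracket,
    expand_reference,
    gate_sample,
    identify_mps_stutters,
    parse_mps_table,
    recalc_thresholds,
    stutter_sequences,
)


def rec(seq, reads, locus="TOY", sample="S1", typed="NO"):
    return MPSSequenceRecord(sample, locus, seq, reads, typed)


class TestGate:
    @pytest.mark.parametrize(
        "total,passed", [(93_000, True), (85_000, True), (84_999, False)]
    )
    def test_boundaries(self, thresholds, total, passed):
        assert gate_sample([], thresholds, total_reads=total).passed is passed

    def test_sums_records_without_explicit_total(self, thresholds):
        records = [rec("TCTA" * 11, 50_000), rec("TCTA" * 9, 35_000)]
        assert gate_sample(records, thresholds).passed


class TestRecalcThresholds:
    @pytest.mark.parametrize(
        "reads,expected",
        [(650, (10, 30)), (200, (10, 30)), (0, (10, 30)), (2000, (30, 90))],
    )
    def test_default_percentages(self, toy_locus, thresholds, reads, expected):
        assert recalc_thresholds(reads, toy_locus, thresholds) == expected

    def test_hardfloor_alternative(self, toy_locus):
        thr = ThresholdConfig(recalc_basis="hardfloor")
        assert recalc_thresholds(200, toy_locus, thr) == (10, 30)
        assert recalc_thresholds(2000, toy_locus, thr) == (30, 90)

    @given(reads=st.integers(0, 200_000))
    @settings(max_examples=80, derandomize=True, suppress_health_check=[HealthCheck.function_scoped_fixture])
    def test_at_always_below_it_and_floor_region_constant(
        self, toy_locus, thresholds, reads
    ):
        at, it = recalc_thresholds(reads, toy_locus, thresholds)
        assert at < it
        if reads <= 650:
            assert (at, it) == (10, 30)


class TestBracketNotation:
    def test_pure_repeat(self, toy_locus):
        allele = bracket_sequence("TCTA" * 11, toy_locus)
        assert allele.bracket_notation == "[TCTA]11"
        assert allele.length_allele == AlleleLabel(11)
        assert not allele.is_reference_variant

    def test_isometric_internal_variant(self, toy_locus):
        seq = "TCTA" * 5 + "TCTG" + "TCTA" * 5
        allele = bracket_sequence(seq, toy_locus)
        assert allele.length_allele == AlleleLabel(11)
        assert allele.is_reference_variant
        assert expand_bracket(allele.bracket_notation) == seq

    def test_microvariant(self, toy_locus):
        allele = bracket_sequence("TCTA" * 11 + "TC", toy_locus)
        assert allele.length_allele == AlleleLabel(11, 2)
        assert str(allele.length_allele) == "11.2"

    def test_compound_structure_with_uncounted_block(self, toy_compound):
        seq = "TCTG" * 3 + "TCTA" * 9 + "GGGG"
        allele = bracket_sequence(seq, toy_compound)
        # the fixed GGGG tail is not counted toward the allele number
        assert allele.length_allele == AlleleLabel(12)
        assert expand_bracket(allele.bracket_notation) == seq

    def test_variant_with_uncounted_block_is_parse_error(self, toy_compound):
        seq = "TCTG" * 3 + "TCTA" * 4 + "AAAA" + "TCTA" * 4 + "GGGG"
        with pytest.raises(BracketParseError):
            bracket_sequence(seq, toy_compound)

    @pytest.mark.parametrize("bad", ["", "TC", "TCTN" * 5])
    def test_degenerate_sequences_rejected(self, toy_locus, bad):
        with pytest.raises(BracketParseError):
            bracket_sequence(bad, toy_locus)

    def test_registry_reference_roundtrip(self, registry):
        """expand -> bracket -> expand is the identity over every allele in
        the default registry's reference range."""
        for d in registry:
            lo, hi = d.allele_range
            for k in range(lo, hi + 1):
                seq = expand_reference(d, k)
                allele = bracket_sequence(seq, d)
                assert allele.length_allele == AlleleLabel(k), d.name
                assert expand_bracket(allele.bracket_notation) == seq
                assert not allele.is_reference_variant

    @given(
        runs=st.lists(
            st.tuples(st.sampled_from(["TCTA", "TCTG", "TTTA"]), st.integers(1, 6)),
            min_size=1,
            max_size=5,
        ),
        partial=st.integers(0, 3),
    )
    @settings(max_examples=100, derandomize=True, suppress_health_check=[HealthCheck.function_scoped_fixture])
    def test_random_sequence_roundtrip(self, toy_locus, runs, partial):
        seq = "".join(m * c for m, c in runs) + "TCTA"[:partial]
        allele = bracket_sequence(seq, toy_locus)
        assert expand_bracket(allele.bracket_notation) == seq
        assert allele.length_allele.total_nt(4) == len(seq)


class TestCalling:
    def base_records(self):
        parent = "TCTA" * 11
        return [
            rec(parent, 800, typed="YES"),
            rec("TCTA" * 10, 96),  # 12% minus stutter
        ]

    def test_grey_zone_candidate_not_called(self, toy_locus, thresholds):
        records = self.base_records() + [rec("TCTA" * 14, 19)]
        call = call_mps_locus(records, toy_locus, thresholds)
        # locus reads 915 -> AT=14, IT=42; the 19-read sequence sits between
        assert call.at_reads < 19 < call.it_reads
        assert call.alleles == [AlleleLabel(11)]
        assert [c.allele.length_allele for c in call.grey_zone_candidates] == [
            AlleleLabel(14)
        ]
        assert "grey_zone" in call.qc_flags

    def test_it_boundary_called(self, toy_locus, thresholds):
        records = [rec("TCTA" * 11, 500, typed="YES"), rec("TCTA" * 14, 30)]
        call = call_mps_locus(records, toy_locus, thresholds)
        assert (call.at_reads, call.it_reads) == (10, 30)
        assert call.alleles == [AlleleLabel(11), AlleleLabel(14)]

    def test_all_below_at_is_inconclusive(self, toy_locus, thresholds):
        call = call_mps_locus(
            [rec("TCTA" * 11, 5), rec("TCTA" * 10, 3)], toy_locus, thresholds
        )
        assert call.alleles == []
        assert "low_coverage_inc" in call.qc_flags

    def test_empty_locus_is_clean_dropout(self, toy_locus, thresholds):
        call = call_mps_locus([], toy_locus, thresholds, sample_id="S1")
        assert call.alleles == [] and call.qc_flags == set()

    def test_stutter_attributed_not_called(self, toy_locus, thresholds):
        # 96/800 = 12% <= 20% filter: the n-1 sequence is a stutter
        call = call_mps_locus(self.base_records(), toy_locus, thresholds)
        assert call.alleles == [AlleleLabel(11)]
        assert len(call.stutter_attributed) == 1

    def test_strong_minor_sequence_called(self, toy_locus, thresholds):
        records = [rec("TCTA" * 11, 800, typed="YES"), rec("TCTA" * 10, 400)]
        call = call_mps_locus(records, toy_locus, thresholds)
        assert call.alleles == [AlleleLabel(10), AlleleLabel(11)]


class TestIsoAlleles:
    def test_same_length_different_sequence(self, toy_multi, thresholds):
        seq_ref = "TCTA" * 12
        seq_var = "TCTA" * 6 + "TCTG" + "TCTA" * 5
        call = call_mps_locus(
            [rec(seq_ref, 300, "TOYM", typed="YES"), rec(seq_var, 280, "TOYM")],
            toy_multi,
            thresholds,
        )
        report = detect_iso_alleles(call)
        assert len(report.iso_allele_pairs) == 1
        a, b = report.iso_allele_pairs[0]
        assert a.length_allele == b.length_allele == AlleleLabel(12)

    def test_different_lengths_not_iso(self, toy_multi, thresholds):
        call = call_mps_locus(
            [rec("TCTA" * 12, 300, "TOYM", typed="YES"), rec("TCTA" * 8, 280, "TOYM")],
            toy_multi,
            thresholds,
        )
        assert detect_iso_alleles(call).iso_allele_pairs == []

    def test_variant_homozygote_flagged(self, toy_multi, thresholds):
        seq_var = "TCTA" * 6 + "TCTG" + "TCTA" * 5
        call = call_mps_locus(
            [rec(seq_var, 600, "TOYM", typed="YES")], toy_multi, thresholds
        )
        report = detect_iso_alleles(call)
        assert report.iso_allele_pairs == []
        assert report.variant_homozygote is not None

    def test_single_reference_allele_empty_report(self, toy_multi, thresholds):
        call = call_mps_locus(
            [rec("TCTA" * 12, 600, "TOYM", typed="YES")], toy_multi, thresholds
        )
        report = detect_iso_alleles(call)
        assert report.iso_allele_pairs == [] and report.variant_homozygote is None


class TestStutterIdentification:
    def test_minus_and_plus_ratios(self, toy_locus, thresholds):
        records = [
            rec("TCTA" * 11, 800, typed="YES"),
            rec("TCTA" * 10, 96),
            rec("TCTA" * 12, 40),
        ]
        call = call_mps_locus(records, toy_locus, thresholds)
        obs = identify_mps_stutters(records, call, toy_locus)
        by = {o.stutter_type: o for o in obs}
        assert by[StutterType.MINUS_ONE_REPEAT].ratio_pct == pytest.approx(12.0)
        assert by[StutterType.PLUS_ONE_REPEAT].ratio_pct == pytest.approx(5.0)

    def test_sequence_exactness(self, toy_locus, thresholds):
        """A one-repeat-shorter sequence of a different variant string is
        not the parent's stutter."""
        parent = "TCTA" * 11
        decoy = "TCTA" * 5 + "TCTG" + "TCTA" * 4  # length 10, variant string
        records = [rec(parent, 800, typed="YES"), rec(decoy, 96)]
        call = call_mps_locus(records, toy_locus, thresholds)
        obs = identify_mps_stutters(records, call, toy_locus)
        assert obs == []
        # the decoy is instead called (12% but sequence does not match)
        assert AlleleLabel(10) in call.alleles

    def test_one_repeat_apart_exclusions(self, toy_multi, thresholds):
        a14, a15 = "TCTA" * 14, "TCTA" * 15
        records = [
            rec(a15, 400, "TOYM", typed="YES"),
            rec(a14, 390, "TOYM"),  # true allele + merged stutter of 15
            rec("TCTA" * 13, 47, "TOYM"),
        ]
        call = call_mps_locus(records, toy_multi, thresholds)
        assert call.alleles == [AlleleLabel(14), AlleleLabel(15)]
        obs = identify_mps_stutters(records, call, toy_multi)
        by = {(str(o.parent_allele), o.stutter_type): o for o in obs}
        minus15 = by[("15", StutterType.MINUS_ONE_REPEAT)]
        assert minus15.excluded
        assert minus15.exclusion_reason is ExclusionReason.OVERLAPS_SMALLER_ALLELE
        plus14 = by[("14", StutterType.PLUS_ONE_REPEAT)]
        assert plus14.excluded
        assert plus14.exclusion_reason is ExclusionReason.OVERLAPS_LARGER_ALLELE
        assert not by[("14", StutterType.MINUS_ONE_REPEAT)].excluded


class TestParseTable:
    def test_roundtrip_and_rejects(self):
        text = (
            "sample_id\tlocus\tsequence\treads\ttyped_flag\n"
            "S1\tTOY\tTCTATCTA\t100\tYES\n"
            "S1\tTOY\tNNNN\t50\tNO\n"
            "S1\tTOY\tTCTA\t0\tNO\n"
        )
        records, rejects = parse_mps_table(io.StringIO(text))
        assert len(records) == 1 and len(rejects) == 2

    def test_missing_column(self):
        with pytest.raises(ValueError, match="missing required columns"):
            parse_mps_table(io.StringIO("sample_id\tlocus\n"))


class TestStutterSequences:
    def test_canonical_choice_is_member_of_full_set(self, toy_locus):
        parent = "TCTA" * 5 + "TCTG" + "TCTA" * 5
        full = stutter_sequences(parent, toy_locus, StutterType.MINUS_ONE_REPEAT)
        assert len(full) == 2  # either TCTA run can slip
        assert (
            canonical_stutter_sequence(
                parent, toy_locus, StutterType.MINUS_ONE_REPEAT
            )
            in full
        )
        for s in full:
            assert len(s) == len(parent) - 4
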