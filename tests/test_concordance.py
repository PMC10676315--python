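"""Concordance classification, allele census, balance and t-tests."""

import math

import pytest
from scipy import stats

from ystr_concord.ce_typing import CELocusCall, CalledPeak, Zygosity, call_ce_locus
from ystr_concord.concordance import (
    census_alleles,
    compare_locus,
    compute_balance,
    students_t,
    summarize_stutters,
)
from ystr_concord.locus_model import (
    AlleleLabel,
    ConcordanceStatus,
    ExclusionReason,
    Platform,
    Registry,
    StutterObservation,
    StutterType,
    ThresholdConfig,
)
from ystr_concord.mps_typing import MPSSequenceRecord, call_mps_locus


def ce_call(alleles, locus="TOY", sample="S1", height=2000.0):
    return CELocusCall(
        sample_id=sample,
        locus=locus,
        called=[CalledPeak(AlleleLabel.parse(a), height) for a in alleles],
        filtered=[],
        zygosity=Zygosity.NO_CALL,
        n_input_peaks=len(alleles),
    )


def mps_call(records, locus_def, sample="S1"):
    thr = ThresholdConfig()
    recs = [
        MPSSequenceRecord(sample, locus_def.name, seq, reads, flag)
        for seq, reads, flag in records
    ]
    return call_mps_locus(recs, locus_def, thr, sample_id=sample)


class TestCompareLocus:
    def test_identity_concordant(self, toy_locus):
        m = mps_call([("TCTA" * 13, 600, "YES")], toy_locus)
        rec = compare_locus(ce_call(["13"]), m, toy_locus)
        assert rec.status is ConcordanceStatus.CONCORDANT

    def test_grey_zone_case(self, toy_multi):
        """Heterozygote by CE; MPS shows the larger allele only between the
        analytical and the interpretation threshold."""
        m = mps_call(
            [("TCTA" * 14, 280, "YES"), ("TCTA" * 13, 34, "NO"), ("TCTA" * 19, 19, "NO")],
            toy_multi,
        )
        assert m.alleles == [AlleleLabel(14)]
        rec = compare_locus(ce_call(["14", "19"], "TOYM"), m, toy_multi)
        assert rec.status is ConcordanceStatus.APPARENT_DISCORDANT_GREY_ZONE

    def test_near_miss_stays_discordant(self, toy_multi):
        # CE-only allele 18 does not match the grey-zone candidate 19
        m = mps_call(
            [("TCTA" * 14, 280, "YES"), ("TCTA" * 19, 19, "NO")], toy_multi
        )
        rec = compare_locus(ce_call(["14", "18"], "TOYM"), m, toy_multi)
        assert rec.status is ConcordanceStatus.DISCORDANT

    def test_true_discordance(self, toy_locus):
        m = mps_call([("TCTA" * 12, 600, "YES")], toy_locus)
        rec = compare_locus(ce_call(["13"]), m, toy_locus)
        assert rec.status is ConcordanceStatus.DISCORDANT

    def test_low_coverage_excluded(self, toy_locus):
        m = mps_call([("TCTA" * 13, 5, "NO")], toy_locus)
        rec = compare_locus(ce_call(["13"]), m, toy_locus)
        assert rec.status is ConcordanceStatus.EXCLUDED_INCONCLUSIVE

    def test_duplication_confirmed(self, toy_locus):
        m = mps_call(
            [("TCTA" * 15, 600, "YES"), ("TCTA" * 12, 540, "NO")], toy_locus
        )
        rec = compare_locus(ce_call(["12", "15"]), m, toy_locus)
        assert rec.status is ConcordanceStatus.CONCORDANT
        assert rec.notes == "duplication confirmed"

    def test_deletion_confirmed(self, toy_locus, thresholds):
        m = call_mps_locus([], toy_locus, thresholds, sample_id="S1")
        rec = compare_locus(ce_call([]), m, toy_locus)
        assert rec.status is ConcordanceStatus.CONCORDANT
        assert rec.notes == "deletion confirmed"

    def test_locus_mismatch_rejected(self, toy_locus, toy_multi):
        m = mps_call([("TCTA" * 13, 600, "YES")], toy_multi)
        with pytest.raises(ValueError):
            compare_locus(ce_call(["13"], "TOY"), m, toy_locus)


class TestCensus:
    def test_shared_reference_allele(self, toy_locus):
        ces = [ce_call(["11"], sample=f"S{i}") for i in range(3)]
        mps = [
            mps_call([("TCTA" * 11, 600, "YES")], toy_locus, sample=f"S{i}")
            for i in range(3)
        ]
        census = census_alleles(ces, mps)
        assert census.length_based["TOY"] == {AlleleLabel(11)}
        assert census.n_sequence_based == 0

    def test_variant_sequence_adds_one(self, toy_locus):
        variant = "TCTA" * 5 + "TCTG" + "TCTA" * 5
        mps = [
            mps_call([("TCTA" * 11, 600, "YES")], toy_locus, sample="S0"),
            mps_call([(variant, 600, "YES")], toy_locus, sample="S1"),
            mps_call([(variant, 500, "YES")], toy_locus, sample="S2"),
        ]
        census = census_alleles([], mps)
        assert census.length_based["TOY"] == {AlleleLabel(11)}
        assert census.n_sequence_based == 1  # deduplicated per locus

    def test_empty(self):
        census = census_alleles([], [])
        assert census.n_length_based == 0 and census.n_sequence_based == 0


@pytest.fixture()
def multi_registry(toy_multi):
    return Registry([toy_multi], ThresholdConfig())


class TestBalance:
    def test_mps_reads_280_218(self, toy_multi, multi_registry):
        m = mps_call(
            [("TCTA" * 14, 280, "YES"), ("TCTA" * 11, 218, "NO")], toy_multi
        )
        obs, excl = compute_balance([m], multi_registry)
        assert len(obs) == 1 and not excl
        assert obs[0].ilb_pct == pytest.approx(77.857142, abs=1e-4)
        assert not obs[0].below_threshold  # above the 60% MPS threshold

    def test_ce_equal_heights(self, toy_multi, multi_registry):
        c = ce_call(["12", "14"], "TOYM", height=500.0)
        obs, _ = compute_balance([c], multi_registry)
        assert obs[0].ilb_pct == 100.0

    def test_triallelic_excluded(self, toy_multi, multi_registry):
        m = mps_call(
            [
                ("TCTA" * 14, 300, "YES"),
                ("TCTA" * 13, 290, "NO"),
                ("TCTA" * 12, 280, "NO"),
            ],
            toy_multi,
        )
        assert len(m.alleles) == 3
        obs, excl = compute_balance([m], multi_registry)
        assert obs == [] and len(excl) == 1

    def test_homozygote_skipped(self, toy_multi, multi_registry):
        m = mps_call([("TCTA" * 14, 600, "YES")], toy_multi)
        obs, excl = compute_balance([m], multi_registry)
        assert obs == [] and excl == []

    def test_imbalanced_flagged(self, toy_multi, multi_registry):
        m = mps_call(
            [("TCTA" * 14, 500, "YES"), ("TCTA" * 11, 250, "NO")], toy_multi
        )
        obs, _ = compute_balance([m], multi_registry)
        assert obs[0].below_threshold  # 50% < 60%


class TestStudentsT:
    def test_worked_example(self):
        res = students_t([10, 12, 14], [11, 13, 15])
        assert res.t == pytest.approx(-0.6124, abs=5e-5)
        assert res.df == 4
        assert res.ci_low < (res.mean_x - res.mean_y) < res.ci_high

    def test_identical_groups(self):
        res = students_t([1, 2, 3], [1, 2, 3])
        assert res.t == 0.0 and res.p == 1.0

    def test_constant_equal_groups(self):
        res = students_t([5, 5, 5], [5, 5])
        assert res.t == 0.0 and res.p == 1.0

    def test_insufficient_n(self):
        with pytest.raises(ValueError):
            students_t([5], [1, 2])

    def test_matches_scipy(self):
        x = [87.0, 91.5, 84.2, 88.8, 90.1]
        y = [75.3, 80.2, 71.9, 78.4]
        res = students_t(x, y)
        ref = stats.ttest_ind(x, y, equal_var=True)
        assert res.t == pytest.approx(ref.statistic, rel=1e-12)
        assert res.p == pytest.approx(ref.pvalue, rel=1e-12)
        welch = students_t(x, y, welch=True)
        ref_w = stats.ttest_ind(x, y, equal_var=False)
        assert welch.t == pytest.approx(ref_w.statistic, rel=1e-12)
        assert welch.p == pytest.approx(ref_w.pvalue, rel=1e-12)


def _obs(ratio, sample="S1", platform=Platform.CE, excluded=False, locus="TOY"):
    return StutterObservation(
        sample_id=sample,
        locus=locus,
        platform=platform,
        parent_allele=AlleleLabel(12),
        stutter_type=StutterType.MINUS_ONE_REPEAT,
        ratio_pct=ratio,
        excluded=excluded,
        exclusion_reason=(
            ExclusionReason.OVERLAPS_SMALLER_ALLELE
            if excluded
            else ExclusionReason.NONE
        ),
    )


class TestSummaries:
    def test_mean_and_detection_frequency(self, toy_locus):
        reg = Registry([toy_locus], ThresholdConfig())
        obs = [_obs(10, "S1"), _obs(12, "S2"), _obs(14, "S3")]
        summary, _ = summarize_stutters(
            obs, reg, {("TOY", Platform.CE, ""): 4}
        )
        row = summary.iloc[0]
        assert row.n == 3
        assert row.mean_pct == pytest.approx(12.0)
        assert row.detection_frequency == pytest.approx(0.75)
        assert row.n_above_filter == 0

    def test_excluded_omitted_from_statistics(self, toy_locus):
        reg = Registry([toy_locus], ThresholdConfig())
        obs = [_obs(10, "S1"), _obs(12, "S2"), _obs(80, "S3", excluded=True)]
        summary, _ = summarize_stutters(obs, reg)
        assert summary.iloc[0].n == 2
        assert summary.iloc[0].mean_pct == pytest.approx(11.0)

    def test_above_filter_counted(self, toy_locus):
        reg = Registry([toy_locus], ThresholdConfig())
        obs = [_obs(10), _obs(16)]  # CE minus filter is 15%
        summary, _ = summarize_stutters(obs, reg)
        assert summary.iloc[0].n_above_filter == 1

    def test_no_observations_empty_frame(self, toy_locus):
        reg = Registry([toy_locus], ThresholdConfig())
        summary, ttests = summarize_stutters([], reg)
        assert summary.empty and ttests.empty

    def test_ttest_attached_per_locus(self, toy_locus):
        reg = Registry([toy_locus], ThresholdConfig())
        obs = [_obs(r, f"S{i}") for i, r in enumerate([10, 11, 12])] + [
            _obs(r, f"S{i}", platform=Platform.MPS)
            for i, r in enumerate([13, 14, 15])
        ]
        _, ttests = summarize_stutters(obs, reg)
        assert len(ttests) == 1
        assert ttests.iloc[0].p < 0.05
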