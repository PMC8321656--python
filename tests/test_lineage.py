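"""Donor-overlap statistics, sex discordance, tri-classification, verdicts."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from graftrace.lineage import (
    DecisionThresholds,
    LineageEvidence,
    OverlapStats,
    SharedVariantThresholds,
    classify_shared_coding,
    count_sex_discordant,
    decide_transmission,
    intersect_profiles,
    overlap_with_donor,
    round_half_away,
)
from graftrace.variants import AnnotatedVariant, SampleProfile, VariantKey

from conftest import bulk_profile, make_observed


class TestOverlap:
    def test_study_percentages(self):
        """23,246 of 27,182 rounds to 85.5%; 22,719 of 25,280 to 90%."""
        profile = bulk_profile(27_182, "om", "recipient_metastasis", start_pos=1)
        donor = SampleProfile(
            "donor", "donor_tumor", "male",
            list(bulk_profile(23_246, "a", start_pos=1))
            + list(bulk_profile(22_719, "b", start_pos=1_000_000)),
        )
        removed = bulk_profile(25_280, "rm", start_pos=1_000_000)
        stats = overlap_with_donor(profile, donor, removed)
        assert stats.shared_with_donor == 23_246
        assert stats.percent_shared == 85.5
        assert stats.common_shared == 22_719
        assert stats.percent_common_shared == 90

    def test_disjoint_profiles(self):
        profile = bulk_profile(100, "p", start_pos=1)
        donor = bulk_profile(100, "d", "donor_tumor", start_pos=10_000)
        stats = overlap_with_donor(profile, donor)
        assert stats.shared_with_donor == 0 and stats.percent_shared == 0.0

    def test_rounding_half_away_from_zero(self):
        # 1/8 = 12.5% -> 13 at integer precision; 85.45% -> 85.5 at one decimal
        profile = bulk_profile(8, "p", start_pos=1)
        donor = bulk_profile(1, "d", "donor_tumor", start_pos=1)
        removed = bulk_profile(8, "rm", start_pos=1)
        stats = overlap_with_donor(profile, donor, removed)
        assert stats.percent_common_shared == 13
        assert round_half_away(85.45, 1) == 85.5
        assert round_half_away(-0.5) == -1.0

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            OverlapStats(10, 11, 110.0, 0, 0, 0)


class TestSexDiscordance:
    def _profile(self, n_y):
        variants = [make_observed(chrom="Y", pos=1000 + i) for i in range(n_y)]
        variants += [make_observed(chrom="1", pos=i + 1) for i in range(10)]
        return SampleProfile("p", "recipient_metastasis", "female", variants)

    def test_female_recipient_male_donor_counts_chry(self):
        count, flag = count_sex_discordant(self._profile(20), "female", "male")
        assert count == 20 and flag is True

    def test_same_sex_not_applicable(self):
        count, flag = count_sex_discordant(self._profile(20), "female", "female")
        assert count is None and flag is False

    def test_no_chry_no_flag(self):
        count, flag = count_sex_discordant(self._profile(0), "female", "male")
        assert count == 0 and flag is False


class TestIntersect:
    def test_identical_profiles(self):
        p = bulk_profile(30, "a", fclass="nonsynonymous")
        assert intersect_profiles([p, p]) == p.ordered_keys()

    def test_with_empty_is_empty(self):
        p = bulk_profile(30, "a")
        assert intersect_profiles([p, SampleProfile("e", "recipient_blood")]) == []

    def test_fewer_than_two_rejected(self):
        with pytest.raises(ValueError):
            intersect_profiles([bulk_profile(5, "a")])

    def test_coding_only_restriction(self):
        coding = make_observed(pos=1, fclass="nonsense")
        noncoding = make_observed(pos=2, fclass="non_exonic_or_ncRNA")
        p1 = SampleProfile("a", "recipient_tumor", "unknown", [coding, noncoding])
        p2 = SampleProfile("b", "recipient_tumor", "unknown", [coding, noncoding])
        assert len(intersect_profiles([p1, p2], coding_only=False)) == 2
        assert intersect_profiles([p1, p2], coding_only=True) == [coding.key]


def _annot(pos, exac=None, fclass="nonsynonymous"):
    freqs = {} if exac is None else {"ExAC": exac}
    return AnnotatedVariant(VariantKey("3", pos, "G", "A"), fclass, db_freqs=freqs)


class TestClassifySharedCoding:
    @pytest.mark.parametrize(
        "exac, donor_af, expected",
        [
            (0.00005, 0.3, "probably_somatic"),        # below the somatic cap
            (0.000094, 0.3, "probably_somatic"),       # at the cap (inclusive)
            (None, 0.3, "probably_somatic"),           # unobserved in ExAC
            (0.0005, 0.50, "rare_donor_germline_exac"),  # in the ExAC band
            (0.0001, 0.3, "rare_donor_germline_exac"),
            (0.0009, 0.3, "rare_donor_germline_exac"),
            (0.005, 0.50, "donor_het_germline_af"),    # only the AF band fits
            (0.005, 0.49, "donor_het_germline_af"),
            (0.005, 0.51, "donor_het_germline_af"),
            (0.000097, 0.3, "unclassified"),           # the gap between bands
            (0.005, 0.3, "unclassified"),
            (0.005, None, "unclassified"),             # AF rule unreachable
        ],
    )
    def test_band_assignment(self, exac, donor_af, expected):
        out = classify_shared_coding([(_annot(100, exac), donor_af)])
        assert [lbl for lbl, vs in out.items() if vs] == [expected]

    def test_study_counts(self):
        """137 below-band + 68 in-band + 33 AF-band classify as (137, 68, 33)."""
        items, pos = [], 1
        for _ in range(137):
            items.append((_annot(pos, exac=0.00005), 0.3)); pos += 1
        for _ in range(68):
            items.append((_annot(pos, exac=0.0005), 0.3)); pos += 1
        for _ in range(33):
            items.append((_annot(pos, exac=0.005), 0.50)); pos += 1
        out = classify_shared_coding(items)
        assert len(out["probably_somatic"]) == 137
        assert len(out["rare_donor_germline_exac"]) == 68
        assert len(out["donor_het_germline_af"]) == 33
        assert len(out["unclassified"]) == 0

    def test_partition_and_oracle_equivalence(self):
        """Vectorized-free rule agrees with a literal per-variant if-chain
        on 10,000 random inputs, and the labels partition the input."""
        rng = np.random.default_rng(7)
        thresholds = SharedVariantThresholds()
        items = []
        for i in range(10_000):
            exac = None if rng.random() < 0.3 else float(rng.uniform(0, 0.002))
            donor_af = None if rng.random() < 0.1 else float(rng.uniform(0, 1))
            items.append((_annot(i + 1, exac), donor_af))
        out = classify_shared_coding(items, thresholds)
        assert sum(len(v) for v in out.values()) == len(items)

        for annot, donor_af in items:
            exac = annot.db_freqs.get("ExAC")
            if exac is None or exac <= 0.000094:
                expected = "probably_somatic"
            elif 0.0001 <= exac <= 0.0009:
                expected = "rare_donor_germline_exac"
            elif donor_af is not None and 0.49 <= donor_af <= 0.51:
                expected = "donor_het_germline_af"
            else:
                expected = "unclassified"
            assert annot in out[expected]

    def test_threshold_ordering_enforced(self):
        with pytest.raises(ValueError):
            SharedVariantThresholds(exac_somatic_max=0.5)


def _evidence(percent_shared, chry=None, flag=False, drivers=()):
    n = 1000
    shared = int(round(percent_shared / 100 * n))
    stats = OverlapStats(n, shared, percent_shared, 0, 0, 0)
    return LineageEvidence(stats, chry, flag, {}, tuple(drivers))


class TestDecision:
    def test_study_evidence_is_transmitted(self):
        decision = decide_transmission(
            _evidence(85.5, chry=20, flag=True, drivers=("BRAF", "PIK3CA"))
        )
        assert decision.verdict == "transmitted"
        assert set(decision.fired_rules) == {"overlap", "sex_discordance",
                                             "shared_drivers"}

    def test_clean_profile_not_transmitted(self):
        decision = decide_transmission(_evidence(0.8, chry=0))
        assert decision.verdict == "not_transmitted"

    def test_middle_ground_indeterminate(self):
        assert decide_transmission(_evidence(40.0)).verdict == "indeterminate"

    def test_chry_alone_suffices(self):
        decision = decide_transmission(_evidence(1.0, chry=6, flag=True))
        assert decision.verdict == "transmitted"
        assert decision.fired_rules == ("sex_discordance",)

    def test_flag_blocks_clean_verdict(self):
        decision = decide_transmission(_evidence(1.0, chry=2, flag=True))
        assert decision.verdict == "indeterminate"

    @settings(derandomize=True, max_examples=200)
    @given(
        pct=st.floats(0, 100),
        t1=st.floats(10, 100),
        t2=st.floats(10, 100),
    )
    def test_overlap_threshold_monotonicity(self, pct, t1, t2):
        """Raising the overlap threshold never flips not_transmitted into
        transmitted."""
        lo, hi = sorted((t1, t2))
        ev = _evidence(round(pct, 1))
        v_lo = decide_transmission(ev, DecisionThresholds(overlap_threshold=lo)).verdict
        v_hi = decide_transmission(ev, DecisionThresholds(overlap_threshold=hi)).verdict
        assert not (v_lo == "not_transmitted" and v_hi == "transmitted")
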