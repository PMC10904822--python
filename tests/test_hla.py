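"""HLA genotype handling, supertype lookup, and the LOH decision rule."""

import math

import pytest

import timepair as tp
from timepair.hla import HlaLocus, call_lesion_loh, load_supertype_table
from timepair import experiments


def evid(lesion, locus, allele, reads, copy):
    return tp.HlaAlleleEvidence(
        lesion=lesion,
        locus=locus,
        allele=allele,
        unique_read_count=reads,
        estimated_copy_number=copy,
    )


def binom_two_sided_half(k, n):
    """Exact two-sided binomial p at p0=0.5 by direct enumeration (symmetry)."""
    pmf = [math.comb(n, i) * 0.5**n for i in range(n + 1)]
    m = min(k, n - k)
    if 2 * m == n:
        return 1.0
    return sum(pmf[: m + 1]) + sum(pmf[n - m :])


class TestGenotype:
    @pytest.mark.parametrize(
        "a1,a2,expected",
        [
            ("A*02:01", "A*02:01", False),
            ("A*02:01", "A*02:06", True),
        ],
    )
    def test_heterozygosity_at_4_digit_resolution(self, a1, a2, expected):
        g = tp.HlaGenotype(patient="P1", locus="A", allele1=a1, allele2=a2)
        assert tp.is_heterozygous(g) is expected

    def test_different_allele_groups_heterozygous(self):
        g = tp.HlaGenotype(patient="P1", locus="B", allele1="B*15:01", allele2="B*40:01")
        assert tp.is_heterozygous(g)

    def test_malformed_allele_name_raises(self):
        with pytest.raises(tp.ParseError):
            tp.HlaGenotype(patient="P1", locus="A", allele1="A02:01", allele2="A*02:01")

    def test_locus_mismatch_raises(self):
        with pytest.raises(tp.ParseError):
            tp.HlaGenotype(patient="P1", locus="A", allele1="B*15:01", allele2="A*02:01")


class TestSupertypes:
    def test_b1501_is_b62(self):
        g = tp.HlaGenotype(patient="P1", locus="B", allele1="B*15:01", allele2="B*40:01")
        assert "B62" in tp.assign_supertypes(g)

    def test_unknown_allele_maps_to_unclassified(self):
        g = tp.HlaGenotype(patient="P1", locus="C", allele1="C*01:02", allele2="C*07:02")
        assert tp.assign_supertypes(g) == {"unclassified"}

    def test_homozygous_genotype_gives_singleton(self):
        g = tp.HlaGenotype(patient="P1", locus="A", allele1="A*02:01", allele2="A*02:01")
        assert tp.assign_supertypes(g) == {"A02"}

    def test_bundled_table_loads_and_is_consistent(self):
        table = load_supertype_table()
        assert table["B*15:01"] == "B62"
        assert all(k.split("*")[0] in ("A", "B") for k in table)


class TestLohCall:
    def test_balanced_locus_not_loh(self):
        call = tp.call_hla_loh(
            (evid("L1", "A", "A*01:01", 100, 1.0), evid("L1", "A", "A*02:01", 100, 1.0))
        )
        assert call.is_loh is False

    def test_skewed_low_copy_is_loh(self):
        call = tp.call_hla_loh(
            (evid("L1", "A", "A*01:01", 15, 0.2), evid("L1", "A", "A*02:01", 185, 1.7)),
            alpha=0.01,
        )
        assert call.is_loh is True
        assert call.lost_allele == "A*01:01"
        assert call.imbalance_p == pytest.approx(binom_two_sided_half(15, 200), abs=1e-12)
        assert call.imbalance_p < 1e-20

    def test_copy_condition_alone_is_not_enough(self):
        # conjunction required: copy < 0.5 but imbalance not significant
        call = tp.call_hla_loh(
            (evid("L1", "A", "A*01:01", 95, 0.4), evid("L1", "A", "A*02:01", 105, 1.5))
        )
        assert binom_two_sided_half(95, 200) > 0.01
        assert call.is_loh is False

    def test_imbalance_alone_is_not_enough(self):
        call = tp.call_hla_loh(
            (evid("L1", "A", "A*01:01", 15, 0.7), evid("L1", "A", "A*02:01", 185, 1.3))
        )
        assert call.is_loh is False

    def test_symmetric_in_allele_order(self):
        a = evid("L1", "B", "B*15:01", 30, 0.3)
        b = evid("L1", "B", "B*40:01", 170, 1.6)
        c1 = tp.call_hla_loh((a, b))
        c2 = tp.call_hla_loh((b, a))
        assert c1.is_loh == c2.is_loh
        assert c1.lost_allele == c2.lost_allele == "B*15:01"
        assert c1.imbalance_p == pytest.approx(c2.imbalance_p, abs=1e-12)

    def test_homozygous_locus_flagged_not_raised(self):
        call = tp.call_hla_loh(
            (evid("L1", "A", "A*02:01", 100, 1.0), evid("L1", "A", "A*02:01", 100, 1.0))
        )
        assert call.applicable is False
        assert call.is_loh is False

    def test_exact_binomial_matches_enumeration_on_random_loci(self, rng):
        for _ in range(200):
            n = int(rng.integers(20, 400))
            k = int(rng.integers(0, n + 1))
            call = tp.call_hla_loh(
                (evid("L", "A", "A*01:01", k, 1.0), evid("L", "A", "A*02:01", n - k, 1.0))
            )
            assert call.imbalance_p == pytest.approx(binom_two_sided_half(k, n), rel=1e-9)


class TestCallerCalibration:
    def test_false_positive_rate_below_alpha_on_balanced_loci(self):
        assert experiments.loh_false_positive_rate(300, seed=7) <= 0.01

    def test_sensitivity_high_at_minor_copy_02(self):
        assert experiments.loh_sensitivity(300, seed=7) >= 0.95


class TestSummarize:
    def _design(self):
        return tp.PairedDesign.from_mapping(
            {f"P{i}": (f"P{i}_AD", f"P{i}_SQ") for i in range(1, 6)}
        )

    def _call(self, lesion, is_loh):
        return tp.LohCall(
            lesion=lesion,
            locus=HlaLocus.A,
            lost_allele="A*01:01" if is_loh else None,
            copy_estimate=0.2 if is_loh else 1.0,
            imbalance_p=0.001 if is_loh else 0.8,
            is_loh=is_loh,
        )

    def test_no_positives_gives_zero_percent(self):
        design = self._design()
        calls = [self._call(s, False) for s in design.samples]
        assert tp.summarize_loh(calls, design)["lesion_pct"] == 0.0

    def test_six_of_ten_gives_sixty_percent(self):
        design = self._design()
        positive = {"P1_AD", "P2_AD", "P3_AD", "P2_SQ", "P3_SQ", "P4_SQ"}
        calls = [self._call(s, s in positive) for s in design.samples]
        summary = tp.summarize_loh(calls, design)
        assert summary["lesion_pct"] == pytest.approx(60.0)
        assert summary["adc_pct"] == pytest.approx(60.0)
        assert summary["sqcc_pct"] == pytest.approx(60.0)
        assert summary["patient_pct"] == pytest.approx(80.0)  # P5 negative

    def test_unknown_lesion_rejected(self):
        design = self._design()
        with pytest.raises(tp.DesignError):
            tp.summarize_loh([self._call("P9_AD", True)], design)

    def test_lesion_positive_if_any_locus_lost(self):
        design = self._design()
        calls = [self._call(s, False) for s in design.samples]
        extra = tp.LohCall(
            lesion="P1_AD",
            locus=HlaLocus.B,
            lost_allele="B*15:01",
            copy_estimate=0.3,
            imbalance_p=0.0001,
            is_loh=True,
        )
        summary = tp.summarize_loh(calls + [extra], design)
        assert summary["lesions_positive"] == 1


class TestEvidenceTable:
    def test_call_lesion_loh_groups_by_locus(self, default_bundle):
        calls = call_lesion_loh(default_bundle.hla_evidence)
        assert len(calls) == 3 * len(default_bundle.design.samples)

    def test_planted_truth_recovered_on_default_bundle(self, default_bundle):
        calls = call_lesion_loh(default_bundle.hla_evidence)
        truth = default_bundle.truth.loh_status
        for call in calls:
            assert call.is_loh == truth[call.lesion][call.locus.value]
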