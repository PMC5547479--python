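"""AI score, classification, 2x2 chi-square, and cross-trait merging."""

import math

import numpy as np
import pytest

from poolai.imbalance import (
    ClassifyThresholds,
    Exclusive,
    GroupFrequencies,
    ImbalanceClass,
    TraitDesign,
    ZeroCoverageError,
    chi_square_2x2,
    classify_imbalance,
    imbalance_score,
    merge_traits,
    pool_group_frequencies,
    score_site,
)
from poolai.variant_io import PooledSiteCount, SnpKey

KEY = SnpKey("chr1", 100, "A", "G")


def counts(fam_to_counts):
    return [
        PooledSiteCount(f, "chr1", 100, "A", "G", r, a)
        for f, (r, a) in fam_to_counts.items()
    ]


def gf(a_high, b_high, a_low, b_low, trait="t"):
    return GroupFrequencies(KEY, trait, a_high, b_high, a_low, b_low)


DESIGN = TraitDesign("t", ("H1", "H2", "H3"), ("L1", "L2", "L3"))


class TestGroupFrequencies:
    def test_counts_summed_within_groups(self):
        # high families alt counts 30+20, ref 10+20 -> fA_high = 50/80
        g = pool_group_frequencies(
            counts({"H1": (10, 30), "H2": (20, 20), "L1": (30, 10)}), DESIGN
        )
        assert g.fa_high == pytest.approx(50 / 80)
        assert g.fa_low == pytest.approx(0.25)
        assert g.fa_high + g.fb_high == pytest.approx(1.0)

    def test_single_family_groups_pass_through(self):
        g = pool_group_frequencies(counts({"H1": (12, 4), "L1": (7, 9)}), DESIGN)
        assert (g.count_a_high, g.count_b_high) == (4, 12)

    def test_zero_coverage_in_a_group_raises(self):
        with pytest.raises(ZeroCoverageError):
            pool_group_frequencies(counts({"H1": (10, 5)}), DESIGN)

    def test_families_outside_the_design_are_ignored(self):
        g1 = pool_group_frequencies(
            counts({"H1": (10, 10), "L1": (10, 10), "XX": (0, 99)}), DESIGN
        )
        assert (g1.count_a_high, g1.count_a_low) == (10, 10)


class TestImbalanceScore:
    def test_hand_arithmetic(self):
        # fA_high=0.8, fA_low=0.4 -> (0.8/0.2)/(0.4/0.6) = 6.0
        assert imbalance_score(gf(80, 20, 40, 60)) == pytest.approx(6.0)

    def test_identical_frequencies_score_one(self):
        assert imbalance_score(gf(30, 70, 3, 7)) == pytest.approx(1.0)

    def test_alt_absent_in_low_group_is_exclusive_high(self):
        assert imbalance_score(gf(15, 25, 0, 40)) is Exclusive.HIGH
        assert imbalance_score(gf(0, 40, 15, 25)) is Exclusive.LOW

    def test_monomorphic_in_both_groups_rejected(self):
        with pytest.raises(ValueError, match="monomorphic"):
            imbalance_score(gf(0, 40, 0, 25))

    def test_score_is_scale_invariant_within_a_group(self):
        s1 = imbalance_score(gf(30, 10, 10, 30))
        s2 = imbalance_score(gf(300, 100, 10, 30))
        assert s1 == pytest.approx(s2)


class TestClassify:
    @pytest.mark.parametrize(
        "score,expected",
        [
            (6.0, ImbalanceClass.AMPLIFICATION),
            (2.0, ImbalanceClass.AMPLIFICATION),  # inclusive threshold
            (1.99, ImbalanceClass.NONE),
            (1.0, ImbalanceClass.NONE),
            (0.5, ImbalanceClass.LOH),
            (0.51, ImbalanceClass.NONE),
            (0.1, ImbalanceClass.LOH),
            (Exclusive.HIGH, ImbalanceClass.EXCLUSIVE_HIGH),
            (Exclusive.LOW, ImbalanceClass.EXCLUSIVE_LOW),
        ],
    )
    def test_thresholds(self, score, expected):
        assert classify_imbalance(score) is expected

    def test_strict_mode_excludes_boundary(self):
        thr = ClassifyThresholds(inclusive=False)
        assert classify_imbalance(2.0, thr) is ImbalanceClass.NONE
        assert classify_imbalance(2.01, thr) is ImbalanceClass.AMPLIFICATION

    def test_non_reciprocal_thresholds_warn(self):
        with pytest.warns(UserWarning, match="reciprocal"):
            ClassifyThresholds(amplification=2.0, loh=0.4)


def chi2_oracle(a, b, c, d):
    """Textbook Pearson chi-square on [[a,b],[c,d]], p via the closed form
    for 1 df: p = erfc(sqrt(x/2))."""
    n = a + b + c + d
    stat = 0.0
    for obs, row, col in ((a, a + b, a + c), (b, a + b, b + d),
                          (c, c + d, a + c), (d, c + d, b + d)):
        e = row * col / n
        stat += (obs - e) ** 2 / e
    return stat, math.erfc(math.sqrt(stat / 2.0))


class TestChiSquare:
    def test_strong_association(self):
        stat, p = chi_square_2x2((30, 10), (10, 30))
        assert stat == pytest.approx(20.0)
        assert p == pytest.approx(7.744e-6, rel=1e-3)

    def test_no_association(self):
        stat, p = chi_square_2x2((20, 20), (20, 20))
        assert stat == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_zero_marginal_is_undefined_not_an_exception(self):
        stat, p = chi_square_2x2((15, 0), (12, 0))
        assert math.isnan(stat) and math.isnan(p)

    def test_agrees_with_closed_form_oracle_on_random_tables(self):
        rng = np.random.default_rng(202)
        for _ in range(1000):
            a, b, c, d = rng.integers(1, 500, size=4)
            stat, p = chi_square_2x2((a, b), (c, d))
            ostat, op = chi2_oracle(a, b, c, d)
            assert stat == pytest.approx(ostat, abs=1e-10)
            assert p == pytest.approx(op, abs=1e-10)


class TestReciprocity:
    def test_swapping_groups_inverts_score_and_swaps_classes(self):
        rng = np.random.default_rng(77)
        swap = {
            ImbalanceClass.AMPLIFICATION: ImbalanceClass.LOH,
            ImbalanceClass.LOH: ImbalanceClass.AMPLIFICATION,
            ImbalanceClass.NONE: ImbalanceClass.NONE,
            ImbalanceClass.EXCLUSIVE_HIGH: ImbalanceClass.EXCLUSIVE_LOW,
            ImbalanceClass.EXCLUSIVE_LOW: ImbalanceClass.EXCLUSIVE_HIGH,
        }
        for _ in range(1000):
            a, b, c, d = rng.integers(0, 200, size=4)
            g = gf(a, b + 1, c, d + 1)  # +1 keeps ref allele present
            g_swapped = gf(c, d + 1, a, b + 1)
            try:
                s = imbalance_score(g)
            except ValueError:
                continue  # monomorphic draw
            s_swapped = imbalance_score(g_swapped)
            if isinstance(s, Exclusive):
                assert isinstance(s_swapped, Exclusive) and s is not s_swapped
            else:
                assert s_swapped == pytest.approx(1.0 / s)
            assert classify_imbalance(s_swapped) is swap[classify_imbalance(s)]

    def test_chi_square_is_symmetric_under_group_swap(self):
        assert chi_square_2x2((30, 10), (10, 30)) == chi_square_2x2(
            (10, 30), (30, 10)
        )


class TestScoreSite:
    def test_full_result_fields(self):
        r = score_site(
            counts({"H1": (10, 30), "H2": (20, 20), "L1": (30, 10), "L2": (30, 10)}),
            DESIGN,
        )
        assert r.imbalance_class is ImbalanceClass.AMPLIFICATION
        assert r.significant and r.p_value < 0.05
        assert r.score == pytest.approx((50 / 30) / (20 / 60))


class TestMergeTraits:
    def mk(self, key, trait, cls=ImbalanceClass.AMPLIFICATION):
        g = GroupFrequencies(key, trait, 30, 10, 10, 30)
        from poolai.imbalance import ImbalanceResult

        return ImbalanceResult(key, trait, g, 3.0, cls, 20.0, 1e-5, True)

    def test_membership_and_histogram(self):
        k1, k2 = SnpKey("chr1", 1, "A", "G"), SnpKey("chr1", 2, "C", "T")
        merged = merge_traits(
            {
                "t1": [self.mk(k1, "t1"), self.mk(k2, "t1")],
                "t2": [self.mk(k1, "t2")],
                "t3": [self.mk(k1, "t3")],
            }
        )
        assert merged.sharing_histogram == {1: 1, 3: 1}
        assert len(merged.membership[k1]) == 3

    def test_disjoint_sets_union(self):
        keys = [SnpKey("chr1", i, "A", "G") for i in range(1, 6)]
        merged = merge_traits(
            {"t1": [self.mk(k, "t1") for k in keys[:2]],
             "t2": [self.mk(k, "t2") for k in keys[2:]]}
        )
        assert len(merged.membership) == 5

    def test_non_imbalanced_results_excluded(self):
        k = SnpKey("chr1", 1, "A", "G")
        merged = merge_traits({"t1": [self.mk(k, "t1", ImbalanceClass.NONE)]})
        assert not merged.membership

    def test_multiallelic_positions_reported_distinct(self):
        ka, kb = SnpKey("chr1", 5, "A", "G"), SnpKey("chr1", 5, "A", "T")
        merged = merge_traits({"t1": [self.mk(ka, "t1")], "t2": [self.mk(kb, "t2")]})
        assert len(merged.membership) == 2
        assert merged.multiallelic_positions == ((ka, kb),)
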