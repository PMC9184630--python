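import math

import numpy as np
import pytest

from conftest import make_gt
from timberdna.genodata_io import GenotypeTable
from timberdna.locus_stats import (
    LocusStatsError,
    all_pairs_ld,
    bonferroni,
    hwe_exact_test,
    ld_exact_test,
    locus_summary,
)

import pandas as pd


def _single_locus_gt(pairs):
    return make_gt({"L": pairs})


class TestLocusSummary:
    def test_two_equifrequent_alleles_closed_form(self):
        # large-n HWE genotype proportions for p = q = 0.5
        pairs = [(1, 1)] * 250 + [(1, 2)] * 500 + [(2, 2)] * 250
        s = locus_summary(_single_locus_gt(pairs), "L")
        assert s.He == pytest.approx(0.5, abs=5e-4)
        assert s.PIC == pytest.approx(0.375, abs=1e-12)
        assert s.Ho == pytest.approx(0.5, abs=1e-12)

    def test_monomorphic_degenerate(self):
        s = locus_summary(_single_locus_gt([(1, 1)] * 10), "L")
        assert (s.A, s.Ho, s.He, s.PIC, s.MP, s.PD) == (1, 0.0, 0.0, 0.0, 1.0, 0.0)

    def test_mp_pd_match_brute_force_enumeration(self):
        pairs = [(1, 1), (1, 2), (1, 2), (2, 2), (1, 3), (3, 3), (2, 3), (1, 2), (1, 1), (2, 2)]
        s = locus_summary(_single_locus_gt(pairs), "L")
        from collections import Counter

        counts = Counter(tuple(sorted(p)) for p in pairs)
        mp = sum((c / len(pairs)) ** 2 for c in counts.values())
        assert s.MP == pytest.approx(mp, abs=1e-12)
        assert s.PD == pytest.approx(1 - mp, abs=1e-12)

    def test_unbiased_he_correction(self):
        # 2 individuals, alleles 1/1 and 1/2: p = (0.75, 0.25), 2n/(2n-1) = 4/3
        s = locus_summary(_single_locus_gt([(1, 1), (1, 2)]), "L")
        assert s.He == pytest.approx((4 / 3) * (1 - 0.75**2 - 0.25**2), abs=1e-12)

    def test_he_invariant_to_allele_relabeling(self):
        pairs = [(100, 104), (100, 100), (104, 108), (108, 108), (100, 108)]
        relabeled = [(a + 50, b + 50) for a, b in pairs]
        s1 = locus_summary(_single_locus_gt(pairs), "L")
        s2 = locus_summary(_single_locus_gt(relabeled), "L")
        assert s1.He == s2.He and s1.PIC == s2.PIC and s1.MP == s2.MP

    def test_pic_never_exceeds_he(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            k = rng.integers(2, 8)
            p = rng.dirichlet(np.ones(k))
            draws = rng.choice(k, size=(40, 2), p=p)
            s = locus_summary(_single_locus_gt([tuple(d) for d in 100 + 2 * draws]), "L")
            assert 0 <= s.PIC <= s.He <= 1

    def test_zero_nonmissing_is_an_error(self):
        gt = make_gt({"L": [(-1, -1)]})
        with pytest.raises(LocusStatsError, match="L"):
            locus_summary(gt, "L")


def exact_two_allele_hwe_p(pairs):
    """Full enumeration of the conditional distribution of heterozygote counts."""
    n = len(pairs)
    n_het = sum(1 for a, b in pairs if a != b)
    alleles = [a for p in pairs for a in p]
    uniq = sorted(set(alleles))
    assert len(uniq) == 2
    n1 = alleles.count(uniq[0])
    n2 = 2 * n - n1

    def log_prob(h):
        n11 = (n1 - h) // 2
        n22 = (n2 - h) // 2
        return (
            math.lgamma(n + 1)
            + math.lgamma(n1 + 1)
            + math.lgamma(n2 + 1)
            + h * math.log(2)
            - math.lgamma(2 * n + 1)
            - math.lgamma(n11 + 1)
            - math.lgamma(h + 1)
            - math.lgamma(n22 + 1)
        )

    support = [h for h in range(min(n1, n2) + 1) if (n1 - h) % 2 == 0 and (n2 - h) % 2 == 0]
    probs = {h: math.exp(log_prob(h)) for h in support}
    total = sum(probs.values())
    obs = probs[n_het]
    return sum(p for p in probs.values() if p <= obs * (1 + 1e-9)) / total


class TestHWEExactTest:
    def test_all_homozygotes_strongly_rejected(self):
        pairs = [(1, 1)] * 10 + [(2, 2)] * 10
        p = hwe_exact_test(_single_locus_gt(pairs), "L", n_perm=2000, seed=1)
        assert p < 0.01

    @pytest.mark.parametrize(
        "pairs",
        [
            [(1, 1)] * 10 + [(2, 2)] * 10,
            [(1, 1)] * 6 + [(1, 2)] * 12 + [(2, 2)] * 6,
            [(1, 2)] * 20 + [(1, 1)] * 5 + [(2, 2)] * 5,
        ],
    )
    def test_matches_two_allele_enumeration(self, pairs):
        exact = exact_two_allele_hwe_p(pairs)
        mc = hwe_exact_test(_single_locus_gt(pairs), "L", n_perm=20_000, seed=2)
        assert mc == pytest.approx(exact, abs=0.02)

    def test_monomorphic_reported_as_one(self):
        assert hwe_exact_test(_single_locus_gt([(1, 1)] * 5), "L", n_perm=100, seed=0) == 1.0

    def test_deterministic_under_fixed_seed(self):
        pairs = [(1, 1)] * 8 + [(1, 2)] * 4 + [(2, 2)] * 8
        gt = _single_locus_gt(pairs)
        p1 = hwe_exact_test(gt, "L", n_perm=500, seed=42)
        p2 = hwe_exact_test(gt, "L", n_perm=500, seed=42)
        assert p1 == p2


class TestLDExactTest:
    def test_perfect_association_rejected(self):
        rng = np.random.default_rng(0)
        draws = rng.choice(4, size=(50, 2), p=[0.4, 0.3, 0.2, 0.1])
        pairs = [tuple(d) for d in 100 + 2 * draws]
        gt = make_gt({"A": pairs, "B": pairs})
        p = ld_exact_test(gt, "A", "B", n_perm=1999, seed=3)
        assert p is not None and p <= 0.001

    def test_type_i_error_near_alpha(self):
        rng = np.random.default_rng(7)
        rejections = 0
        reps = 100
        for rep in range(reps):
            a = [tuple(d) for d in 100 + 2 * rng.choice(3, size=(60, 2), p=[0.5, 0.3, 0.2])]
            b = [tuple(d) for d in 200 + 2 * rng.choice(3, size=(60, 2), p=[0.4, 0.4, 0.2])]
            gt = make_gt({"A": a, "B": b})
            p = ld_exact_test(gt, "A", "B", n_perm=200, seed=rep)
            rejections += p < 0.05
        # binomial(100, 0.05): central band
        assert rejections <= 12

    def test_forty_five_pairs_from_ten_loci(self, structured_gt):
        res = all_pairs_ld(structured_gt, "combined", n_perm=5, seed=0)
        assert len(res) == 45

    def test_insufficient_data_flagged_na(self):
        gt = make_gt({"A": [(1, 1)] * 5, "B": [(2, 3)] * 5})
        assert ld_exact_test(gt, "A", "B", n_perm=50, seed=0) is None


class TestBonferroni:
    def test_threshold_for_ten_tests(self):
        flags, thr = bonferroni([0.5] * 10, alpha=0.05)
        assert thr == pytest.approx(0.0050)

    def test_boundary_cases(self):
        flags, thr = bonferroni([0.0049, 0.0051] + [0.5] * 8, alpha=0.05)
        assert flags[0] is True and flags[1] is False

    def test_single_test_reduces_to_alpha(self):
        flags, thr = bonferroni([0.04], alpha=0.05)
        assert thr == 0.05 and flags == [True]
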