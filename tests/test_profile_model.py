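import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from timberdna.allele_db import AlleleFreqDB, GroupFreqs, LocusFreqs, apply_floor
from timberdna.profile_model import (
    ProfileModelError,
    ProfileModelParams,
    extreme_profiles,
    genotype_frequency,
    profile_frequency,
    random_match_probability,
    tie_break_extremes,
)


def _db_from_freqs(loci_freqs: dict[str, dict[int, float]], n: int = 100) -> AlleleFreqDB:
    loci = {}
    for locus, freqs in loci_freqs.items():
        counts = {a: int(round(p * 2 * n)) for a, p in freqs.items()}
        loci[locus] = LocusFreqs(counts=counts, n_typed=n)
    return AlleleFreqDB(grouping="region", groups={"R": GroupFreqs(n_individuals=n, loci=loci)}, loci=list(loci_freqs))


def _genotype_space(alleles):
    return [(a, b) for i, a in enumerate(alleles) for b in alleles[i:]]


class TestGenotypeFrequency:
    def test_product_rule_limit(self):
        p = {1: 0.2, 2: 0.3, 3: 0.5}
        params = ProfileModelParams(theta=0, f=0)
        assert genotype_frequency((1, 2), p, params) == pytest.approx(0.12)

    def test_homozygote_with_inbreeding_closed_form(self):
        p = {1: 0.2, 2: 0.8}
        params = ProfileModelParams(theta=0, f=0.1)
        assert genotype_frequency((1, 1), p, params) == pytest.approx(0.1 * 0.2 + 0.9 * 0.04)

    @pytest.mark.parametrize("theta", [0.0, 0.05, 0.19, 0.45])
    @pytest.mark.parametrize("f", [0.0, 0.08, 0.3])
    def test_unconditional_normalises_over_genotype_space(self, theta, f):
        rng = np.random.default_rng(17)
        freqs = dict(zip(range(5), rng.dirichlet(np.ones(5))))
        params = ProfileModelParams(theta=theta, f=f, mode="unconditional-frequency")
        total = sum(genotype_frequency(g, freqs, params) for g in _genotype_space(list(freqs)))
        assert total == pytest.approx(1.0, abs=1e-12)

    def test_conditional_match_monotone_in_theta_for_rare_alleles(self):
        # homozygotes always; heterozygotes whenever 1/p + 1/q > 5 (both
        # alleles common, e.g. p = q = 0.5, is the known exception)
        freqs = {1: 0.05, 2: 0.1, 3: 0.85}
        grid = np.linspace(0.0, 0.45, 16)
        for g in _genotype_space([1, 2, 3]):
            vals = [
                genotype_frequency(g, freqs, ProfileModelParams(theta=t, mode="conditional-match"))
                for t in grid
            ]
            assert all(b >= a - 1e-12 for a, b in zip(vals, vals[1:]))

    def test_unconditional_heterozygote_decreasing_in_theta(self):
        freqs = {1: 0.3, 2: 0.7}
        grid = np.linspace(0.0, 0.45, 16)
        vals = [
            genotype_frequency((1, 2), freqs, ProfileModelParams(theta=t, f=0.05))
            for t in grid
        ]
        assert all(b <= a for a, b in zip(vals, vals[1:]))

    def test_absent_allele_advises_floor(self):
        with pytest.raises(ProfileModelError, match="floor"):
            genotype_frequency((1, 9), {1: 1.0}, ProfileModelParams())

    def test_conditional_match_reduces_to_product_rule_at_theta_zero(self):
        freqs = {1: 0.25, 2: 0.35, 3: 0.4}
        params = ProfileModelParams(theta=0.0, mode="conditional-match")
        assert genotype_frequency((1, 1), freqs, params) == pytest.approx(0.25**2)
        assert genotype_frequency((1, 2), freqs, params) == pytest.approx(2 * 0.25 * 0.35)

    @given(st.floats(0.0, 0.5))
    @settings(max_examples=30, deadline=None)
    def test_conditional_match_never_below_product_rule(self, theta):
        # the theta correction can only strengthen a homozygote match
        freqs = {1: 0.05, 2: 0.2, 3: 0.75}
        params = ProfileModelParams(theta=theta, mode="conditional-match")
        for a, p in freqs.items():
            assert genotype_frequency((a, a), freqs, params) >= p**2 - 1e-12


class TestProfileFrequency:
    def test_single_locus_reduces_to_genotype_frequency(self):
        db = _db_from_freqs({"L1": {1: 0.25, 2: 0.75}})
        params = ProfileModelParams(theta=0.03, f=0.05)
        assert profile_frequency({"L1": (1, 2)}, db, "R", params) == pytest.approx(
            genotype_frequency((1, 2), {1: 0.25, 2: 0.75}, params)
        )

    def test_all_het_product_rule(self):
        freqs = {f"L{i}": {1: 0.25, 2: 0.75} for i in range(10)}
        db = _db_from_freqs(freqs)
        params = ProfileModelParams(theta=0, f=0)
        expected = (2 * 0.25 * 0.75) ** 10
        assert profile_frequency({l: (1, 2) for l in freqs}, db, "R", params) == pytest.approx(expected)

    def test_two_locus_hand_product(self):
        db = _db_from_freqs({"L1": {1: 0.2, 2: 0.8}, "L2": {3: 0.5, 4: 0.5}})
        params = ProfileModelParams(theta=0.1, f=0.05)
        byhand = ((1 - 0.05) * 2 * 0.2 * 0.8 * 0.9) * (
            0.05 * 0.5 + 0.95 * 0.5 * (0.1 + 0.9 * 0.5)
        )
        assert profile_frequency({"L1": (1, 2), "L2": (3, 3)}, db, "R", params) == pytest.approx(byhand)

    def test_incomplete_profile_rejected(self):
        db = _db_from_freqs({"L1": {1: 1.0}, "L2": {2: 1.0}})
        with pytest.raises(ProfileModelError, match="L2"):
            profile_frequency({"L1": (1, 1)}, db, "R", ProfileModelParams())

    def test_invariant_to_locus_order(self):
        db1 = _db_from_freqs({"L1": {1: 0.3, 2: 0.7}, "L2": {3: 0.6, 4: 0.4}})
        db2 = _db_from_freqs({"L2": {3: 0.6, 4: 0.4}, "L1": {1: 0.3, 2: 0.7}})
        prof = {"L1": (1, 2), "L2": (4, 4)}
        params = ProfileModelParams(theta=0.02, f=0.01)
        assert profile_frequency(prof, db1, "R", params) == pytest.approx(
            profile_frequency(prof, db2, "R", params)
        )


class TestExtremeProfiles:
    def test_symmetric_two_allele_case(self):
        freqs = {f"L{i}": {1: 0.5, 2: 0.5} for i in range(10)}
        db = _db_from_freqs(freqs)
        common, rare = extreme_profiles(db, "R", ProfileModelParams())
        assert common == pytest.approx(0.5**10)
        assert rare == pytest.approx(0.5**10)

    def test_common_exceeds_rare(self):
        freqs = {f"L{i}": {1: 0.5, 2: 0.3, 3: 0.15, 4: 0.05} for i in range(5)}
        db = _db_from_freqs(freqs)
        common, rare = extreme_profiles(db, "R", ProfileModelParams(theta=0.05, f=0.08))
        assert common > rare

    def test_rarest_uses_floored_frequencies(self):
        # one allele far below the floor: the rarest profile must use the floor
        db = _db_from_freqs({"L1": {1: 0.001, 2: 0.009, 3: 0.99}}, n=500)
        db = apply_floor(db, 0.0066)
        _, rare = extreme_profiles(db, "R", ProfileModelParams())
        assert rare == pytest.approx(2 * 0.0066 * 0.009)

    def test_locus_with_single_allele_rejected(self):
        db = _db_from_freqs({"L1": {1: 1.0}})
        with pytest.raises(ProfileModelError):
            extreme_profiles(db, "R", ProfileModelParams())


class TestTieBreaks:
    def test_tied_frequencies_prefer_smaller_fragment(self):
        common, rare = tie_break_extremes({120: 0.4, 124: 0.4, 130: 0.2})
        assert common == (120, 124)

    def test_clear_ordering(self):
        common, rare = tie_break_extremes({120: 0.5, 124: 0.3, 130: 0.2})
        assert common == (120, 124) and rare == (124, 130)

    def test_all_equifrequent_takes_two_smallest(self):
        common, rare = tie_break_extremes({130: 0.25, 120: 0.25, 124: 0.25, 140: 0.25})
        assert common == (120, 124) and rare == (120, 124)


class TestRandomMatchProbability:
    @pytest.mark.parametrize(
        "freq,text",
        [
            (2.69e-7, "1 in 3.72 million"),
            (1.84e-14, "1 in 54.3 trillion"),
            (1.06e-7, "1 in 9.43 million"),
            (4.03e-16, "1 in 2.48 quadrillion"),
            (0.5, "1 in 2"),
        ],
    )
    def test_reciprocal_formatting(self, freq, text):
        assert random_match_probability(freq) == text

    def test_zero_frequency_rejected(self):
        with pytest.raises(ProfileModelError):
            random_match_probability(0.0)
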