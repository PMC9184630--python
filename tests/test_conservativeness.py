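import numpy as np
import pytest

from conftest import make_gt
from timberdna.allele_db import AlleleFreqDB, GroupFreqs, LocusFreqs, apply_floor, build_allele_db
from timberdna.conservativeness import (
    CalibrationResult,
    ConservativenessError,
    adjust_theta,
    d_statistic,
    evaluate_conservativeness,
)
from timberdna.profile_model import ProfileModelParams
from timberdna.synthetic_data import SimConfig, simulate_hierarchical_ssr


def _db(loci_freqs, name="G", n=100):
    loci = {
        locus: LocusFreqs(counts={a: int(round(p * 2 * n)) for a, p in fr.items()}, n_typed=n)
        for locus, fr in loci_freqs.items()
    }
    return AlleleFreqDB(grouping="population", groups={name: GroupFreqs(n, loci)}, loci=list(loci_freqs))


@pytest.fixture(scope="module")
def region_gt():
    gt = simulate_hierarchical_ssr(
        SimConfig(n_regions=1, pops_per_region=5, n_per_pop=30, n_loci=10,
                  alleles_per_locus=10, theta_region=0, theta_pop=0.05, f_inbreed=0.08, seed=23)
    )
    pop_dbs = apply_floor(build_allele_db(gt, "population"), "auto")
    regional = apply_floor(build_allele_db(gt, "combined"), "auto")
    return gt, pop_dbs, regional


class TestDStatistic:
    def test_identity_databases_give_zero(self):
        db = _db({"L1": {1: 0.3, 2: 0.7}, "L2": {3: 0.5, 4: 0.5}})
        params = ProfileModelParams(theta=0.05, f=0.02)
        rec = d_statistic({"L1": (1, 2), "L2": (3, 3)}, db, db, params, params)
        assert rec.d == 0.0

    def test_two_population_toy_matches_hand_arithmetic(self):
        cognate = _db({"L1": {1: 0.8, 2: 0.2}})
        combined = _db({"L1": {1: 0.5, 2: 0.5}})
        p0 = ProfileModelParams(theta=0.0, f=0.0)
        rec = d_statistic({"L1": (1, 1)}, cognate, combined, p0, p0)
        assert rec.d == pytest.approx(np.log10(0.64) - np.log10(0.25))

    def test_rare_at_home_common_regionally_is_conservative(self):
        cognate = _db({"L1": {1: 0.05, 2: 0.95}})
        combined = _db({"L1": {1: 0.6, 2: 0.4}})
        p0 = ProfileModelParams()
        rec = d_statistic({"L1": (1, 1)}, cognate, combined, p0, p0)
        assert rec.d < 0 and rec.conservative

    def test_antisymmetric_under_database_swap(self):
        a = _db({"L1": {1: 0.7, 2: 0.3}})
        b = _db({"L1": {1: 0.4, 2: 0.6}})
        pa = ProfileModelParams(theta=0.02, f=0.01)
        pb = ProfileModelParams(theta=0.1, f=0.05)
        fwd = d_statistic({"L1": (1, 2)}, a, b, pa, pb)
        rev = d_statistic({"L1": (1, 2)}, b, a, pb, pa)
        assert fwd.d == pytest.approx(-rev.d)


class TestEvaluateConservativeness:
    def test_structured_data_nonconservative_at_raw_theta(self, region_gt):
        gt, pop_dbs, regional = region_gt
        from timberdna.fstatistics import weir_cockerham

        theta0, f, _ = weir_cockerham(gt)
        params = ProfileModelParams(theta=theta0, f=f, mode="conditional-match")
        records, summary = evaluate_conservativeness(gt, pop_dbs, regional, params)
        assert summary["n"] == gt.n_samples
        assert summary["n_nonconservative"] > 0

    def test_deterministic(self, region_gt):
        gt, pop_dbs, regional = region_gt
        params = ProfileModelParams(theta=0.05, f=0.08, mode="conditional-match")
        _, s1 = evaluate_conservativeness(gt, pop_dbs, regional, params)
        _, s2 = evaluate_conservativeness(gt, pop_dbs, regional, params)
        assert s1 == s2

    def test_single_population_region_reduces_to_param_difference(self):
        gt = simulate_hierarchical_ssr(
            SimConfig(n_regions=1, pops_per_region=1, n_per_pop=40, theta_pop=0, f_inbreed=0, seed=2)
        )
        pop_dbs = apply_floor(build_allele_db(gt, "population"), "auto")
        regional = apply_floor(build_allele_db(gt, "combined"), "auto")
        # identical frequencies and theta=0 in both -> every d exactly 0
        params = ProfileModelParams(theta=0.0, f=0.0, mode="conditional-match")
        records, summary = evaluate_conservativeness(gt, pop_dbs, regional, params)
        assert all(abs(r.d) < 1e-12 for r in records)

    def test_incomplete_individuals_excluded(self):
        gt = make_gt(
            {"L1": [(1, 2), (-1, -1)], "L2": [(1, 1), (1, 2)]},
            populations=["p1", "p1"],
        )
        pop_dbs = apply_floor(build_allele_db(gt, "population"), "auto")
        regional = apply_floor(build_allele_db(gt, "combined"), "auto")
        records, summary = evaluate_conservativeness(
            gt, pop_dbs, regional, ProfileModelParams(mode="conditional-match")
        )
        assert summary["n"] == 1


class TestAdjustTheta:
    def test_grid_minimal_theta_with_all_negative_d(self, region_gt):
        gt, pop_dbs, regional = region_gt
        res = adjust_theta(gt, pop_dbs, regional, theta_init=0.05, f=0.08, step=0.005)
        assert res.converged and res.theta_adjusted >= 0.05
        params_at = lambda t: ProfileModelParams(theta=t, f=0.08, mode="conditional-match")
        _, at_adj = evaluate_conservativeness(gt, pop_dbs, regional, params_at(res.theta_adjusted))
        assert at_adj["n_nonconservative"] == 0
        if res.theta_adjusted > 0.05:
            _, below = evaluate_conservativeness(
                gt, pop_dbs, regional, params_at(res.theta_adjusted - 0.005)
            )
            assert below["n_nonconservative"] >= 1

    def test_nonconservative_set_shrinks_monotonically_in_theta(self, region_gt):
        gt, pop_dbs, regional = region_gt
        sets = []
        for theta in (0.02, 0.06, 0.10, 0.14, 0.18):
            records, _ = evaluate_conservativeness(
                gt, pop_dbs, regional, ProfileModelParams(theta=theta, f=0.08, mode="conditional-match")
            )
            sets.append({r.sample_id for r in records if not r.conservative})
        for bigger, smaller in zip(sets, sets[1:]):
            assert smaller <= bigger

    def test_already_conservative_returns_initial(self):
        gt = simulate_hierarchical_ssr(
            SimConfig(n_regions=1, pops_per_region=1, n_per_pop=30, theta_pop=0, f_inbreed=0, seed=4)
        )
        pop_dbs = apply_floor(build_allele_db(gt, "population"), "auto")
        regional = apply_floor(build_allele_db(gt, "combined"), "auto")
        res = adjust_theta(gt, pop_dbs, regional, theta_init=0.1, f=0.0, step=0.005)
        assert res.converged and res.theta_adjusted == 0.1

    def test_theta_max_reached_reports_nonconvergence(self, region_gt):
        gt, pop_dbs, regional = region_gt
        res = adjust_theta(gt, pop_dbs, regional, theta_init=0.01, f=0.08, step=0.005, theta_max=0.01)
        assert not res.converged

    def test_reported_theta_on_printed_grid_precision(self, region_gt):
        gt, pop_dbs, regional = region_gt
        res = adjust_theta(gt, pop_dbs, regional, theta_init=0.0454, f=0.08, step=0.005)
        # four-decimal reporting: representable on the theta_init + k*step grid
        assert res.theta_adjusted == round(res.theta_adjusted, 4)
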