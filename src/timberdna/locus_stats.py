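"""Per-locus descriptive and forensic parameters, exact HWE/LD tests, Bonferroni.

Conventions follow the classic forensic-database toolchain: unbiased
expected heterozygosity He = (2n/(2n-1))(1 - sum p_i^2); matching
probability MP from *observed* genotype proportions (not HWE-expected),
PD = 1 - MP; the Hardy-Weinberg exact test is the Guo-Thompson Monte
Carlo test ranking genotype arrays by their conditional probability given
the allele counts; the pairwise LD test permutes single-locus genotypes
among individuals with a G (log-likelihood-ratio) statistic.

Missing data are deleted pairwise: each locus (each locus pair for LD)
uses every individual with a call there.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy.special import gammaln

from timberdna.genodata_io import MISSING, GenotypeTable


class LocusStatsError(ValueError):
    pass


@dataclass
class LocusSummary:
    """Forensic summary for one locus in one database group."""

    locus: str
    group: str
    n: int  # non-missing individuals
    A: int
    Ho: float
    He: float
    PIC: float
    MP: float
    PD: float
    hwe_p: float | None = None


def _group_mask(gt: GenotypeTable, group: str) -> np.ndarray:
    if group == "combined":
        return np.ones(gt.n_samples, dtype=bool)
    if group in set(gt.samples["population"]):
        return (gt.samples["population"] == group).to_numpy()
    if group in set(r for r in gt.samples["region"] if r is not None):
        return (gt.samples["region"] == group).to_numpy()
    raise LocusStatsError(f"group {group!r} is neither a population, a region nor 'combined'")


def _called(gt: GenotypeTable, locus: str, group: str) -> np.ndarray:
    g = gt.genotypes[locus][_group_mask(gt, group)]
    return g[g[:, 0] != MISSING]


def locus_summary(
    gt: GenotypeTable,
    locus: str,
    group: str = "combined",
    hwe_perm: int | None = None,
    seed: int = 0,
) -> LocusSummary:
    """Compute A, Ho, He, PIC, MP and PD for one locus in one group.

    ``hwe_perm`` adds the Guo-Thompson HWE p-value (None skips the test).
    """
    g = _called(gt, locus, group)
    n = len(g)
    if n == 0:
        raise LocusStatsError(f"no non-missing genotypes at locus {locus} in group {group}")
    alleles, counts = np.unique(g.ravel(), return_counts=True)
    p = counts / counts.sum()
    ho = float(np.mean(g[:, 0] != g[:, 1]))
    sum_p2 = float(np.sum(p**2))
    he = (2 * n) / (2 * n - 1) * (1.0 - sum_p2) if n > 0 else 0.0
    # sum_{i<j} 2 p_i^2 p_j^2 = (sum p^2)^2 - sum p^4
    pic = 1.0 - sum_p2 - (sum_p2**2 - float(np.sum(p**4)))
    genos = np.sort(g, axis=1)
    _, gcounts = np.unique(genos, axis=0, return_counts=True)
    mp = float(np.sum((gcounts / n) ** 2))
    hwe_p = None
    if hwe_perm is not None:
        if len(alleles) >= 2:
            hwe_p = hwe_exact_test(gt, locus, group, n_perm=hwe_perm, seed=seed)
        else:
            hwe_p = 1.0
    return LocusSummary(
        locus=locus, group=group, n=n, A=int(len(alleles)),
        Ho=ho, He=float(he), PIC=float(pic), MP=mp, PD=1.0 - mp, hwe_p=hwe_p,
    )


def _log_conditional_prob(geno_counts: dict[tuple[int, int], int], allele_counts: dict[int, int]) -> float:
    """log P(genotype array | allele counts) under HWE (Levene / Guo-Thompson).

    P = n! * prod_k a_k! * 2^h / ((2n)! * prod_{i<=j} n_ij!)
    """
    n = sum(geno_counts.values())
    two_n = sum(allele_counts.values())
    h = sum(c for (a, b), c in geno_counts.items() if a != b)
    logp = gammaln(n + 1) - gammaln(two_n + 1) + h * np.log(2.0)
    logp += sum(gammaln(c + 1) for c in allele_counts.values())
    logp -= sum(gammaln(c + 1) for c in geno_counts.values())
    return float(logp)


def _geno_count_dict(g: np.ndarray) -> dict[tuple[int, int], int]:
    genos = np.sort(g, axis=1)
    keys, counts = np.unique(genos, axis=0, return_counts=True)
    return {(int(a), int(b)): int(c) for (a, b), c in zip(keys, counts)}


def hwe_exact_test(
    gt: GenotypeTable, locus: str, group: str = "combined", n_perm: int = 10_000, seed: int = 0
) -> float:
    """Monte Carlo exact test of Hardy-Weinberg proportions (Guo-Thompson).

    The 2n observed alleles are repeatedly shuffled into n random diploid
    genotypes; a permutation is as-or-more-extreme when its conditional
    genotype-array probability does not exceed the observed one.
    p = (#extreme + 1) / (n_perm + 1). Deterministic under ``seed``.
    """
    g = _called(gt, locus, group)
    if len(g) == 0:
        raise LocusStatsError(f"no data at {locus} in {group}")
    alleles = g.ravel().copy()
    allele_counts = {int(a): int(c) for a, c in zip(*np.unique(alleles, return_counts=True))}
    if len(allele_counts) < 2:
        return 1.0
    log_obs = _log_conditional_prob(_geno_count_dict(g), allele_counts)
    rng = np.random.default_rng(seed)
    extreme = 0
    for _ in range(n_perm):
        rng.shuffle(alleles)
        perm = alleles.reshape(-1, 2)
        log_perm = _log_conditional_prob(_geno_count_dict(perm), allele_counts)
        if log_perm <= log_obs + 1e-9:
            extreme += 1
    return (extreme + 1) / (n_perm + 1)


def _g_statistic(table: np.ndarray) -> float:
    """G (log-likelihood-ratio) statistic of a contingency table."""
    table = table.astype(float)
    n = table.sum()
    rows = table.sum(axis=1, keepdims=True)
    cols = table.sum(axis=0, keepdims=True)
    expected = rows @ cols / n
    mask = table > 0
    return float(2.0 * np.sum(table[mask] * np.log(table[mask] / expected[mask])))


def ld_exact_test(
    gt: GenotypeTable,
    locus_a: str,
    locus_b: str,
    group: str = "combined",
    n_perm: int = 10_000,
    seed: int = 0,
) -> float | None:
    """Permutation test of genotypic linkage disequilibrium between two loci.

    Individuals' single-locus genotypes at ``locus_b`` are shuffled,
    breaking any association while preserving both marginal genotype
    distributions; the statistic is the G statistic of the two-locus
    genotype contingency table. Returns None (flagged NA) when fewer than
    two distinct genotypes exist at either locus.
    """
    mask = _group_mask(gt, group)
    ga = gt.genotypes[locus_a][mask]
    gb = gt.genotypes[locus_b][mask]
    both = (ga[:, 0] != MISSING) & (gb[:, 0] != MISSING)
    ga, gb = np.sort(ga[both], axis=1), np.sort(gb[both], axis=1)
    if len(ga) < 2:
        return None
    _, ia = np.unique(ga, axis=0, return_inverse=True)
    _, ib = np.unique(gb, axis=0, return_inverse=True)
    ka, kb = ia.max() + 1, ib.max() + 1
    if ka < 2 or kb < 2:
        return None

    def table(idx_b: np.ndarray) -> np.ndarray:
        t = np.zeros((ka, kb), dtype=np.int64)
        np.add.at(t, (ia, idx_b), 1)
        return t

    g_obs = _g_statistic(table(ib))
    rng = np.random.default_rng(seed)
    perm = ib.copy()
    extreme = 0
    for _ in range(n_perm):
        rng.shuffle(perm)
        if _g_statistic(table(perm)) >= g_obs - 1e-9:
            extreme += 1
    return (extreme + 1) / (n_perm + 1)


def all_pairs_ld(
    gt: GenotypeTable, group: str = "combined", n_perm: int = 2_000, seed: int = 0
) -> dict[tuple[str, str], float | None]:
    """LD p-values for every unordered locus pair (C(L,2) tests)."""
    out = {}
    for i, (a, b) in enumerate(combinations(gt.loci, 2)):
        out[(a, b)] = ld_exact_test(gt, a, b, group, n_perm=n_perm, seed=seed + i)
    return out


def bonferroni(pvals: list[float], alpha: float = 0.05) -> tuple[list[bool], float]:
    """Flag p-values significant at the Bonferroni-adjusted threshold alpha/k."""
    if len(pvals) == 0:
        raise LocusStatsError("no p-values supplied")
    threshold = alpha / len(pvals)
    return [p < threshold for p in pvals], threshold
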