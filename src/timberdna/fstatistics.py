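"""Weir-Cockerham coancestry (theta) and inbreeding (f) with locus-bootstrap CIs.

Implements the 1984 variance-component estimators: for each allele at
each locus, components a (among populations), b (among individuals within
populations) and c (within individuals) are computed from population
allele frequencies, heterozygote frequencies and (unequal) sample sizes.
Components are summed over alleles and loci before taking ratios (the
"ratio of averages"):

    theta = sum(a) / sum(a + b + c)
    F     = 1 - sum(c) / sum(a + b + c)
    f     = 1 - sum(c) / sum(b + c)

Confidence intervals resample loci with replacement (the locus is the
bootstrap unit) and report percentile 2.5/97.5 bounds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from timberdna.genodata_io import MISSING, GenotypeTable


class FStatError(ValueError):
    pass


@dataclass
class FStatEstimates:
    level: str
    theta: float
    f: float
    F: float
    theta_ci: tuple[float, float]
    f_ci: tuple[float, float]
    n_boot: int

    @property
    def theta_significant(self) -> bool:
        """True when the 95% CI for theta excludes zero."""
        lo, hi = self.theta_ci
        return lo > 0.0 or hi < 0.0

    @property
    def f_significant(self) -> bool:
        lo, hi = self.f_ci
        return lo > 0.0 or hi < 0.0


def _locus_components(gt: GenotypeTable, labels: np.ndarray, locus: str) -> tuple[float, float, float]:
    """Summed-over-alleles (a, b, c) variance components for one locus."""
    g = gt.genotypes[locus]
    called = g[:, 0] != MISSING
    pops = [p for p in dict.fromkeys(labels)]
    n_i, p_i, h_i, keep_alleles = [], [], [], set()
    for pop in pops:
        sel = (labels == pop) & called
        gp = g[sel]
        if len(gp) == 0:
            continue
        alleles, counts = np.unique(gp.ravel(), return_counts=True)
        keep_alleles.update(int(a) for a in alleles)
        n_i.append(len(gp))
        p_i.append({int(a): c / (2 * len(gp)) for a, c in zip(alleles, counts)})
        het = gp[:, 0] != gp[:, 1]
        h_i.append({int(a): float(np.mean(het & ((gp[:, 0] == a) | (gp[:, 1] == a)))) for a in alleles})
    r = len(n_i)
    if r < 2:
        raise FStatError(f"locus {locus}: fewer than two populations with data")
    n_arr = np.asarray(n_i, dtype=float)
    nbar = n_arr.mean()
    nc = (r * nbar - np.sum(n_arr**2) / (r * nbar)) / (r - 1)
    a_sum = b_sum = c_sum = 0.0
    for allele in sorted(keep_alleles):
        p = np.array([d.get(allele, 0.0) for d in p_i])
        h = np.array([d.get(allele, 0.0) for d in h_i])
        pbar = float(np.sum(n_arr * p) / (r * nbar))
        hbar = float(np.sum(n_arr * h) / (r * nbar))
        s2 = float(np.sum(n_arr * (p - pbar) ** 2) / ((r - 1) * nbar))
        if nbar <= 1:
            raise FStatError(f"locus {locus}: mean sample size must exceed 1")
        a = (nbar / nc) * (s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1))
        b = (nbar / (nbar - 1)) * (pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar)
        c = hbar / 2
        a_sum += a
        b_sum += b
        c_sum += c
    return a_sum, b_sum, c_sum


def _components_by_locus(gt: GenotypeTable, populations: list[str] | None = None) -> np.ndarray:
    if populations is not None:
        gt = gt.subset_populations(populations)
    labels = gt.samples["population"].to_numpy()
    if len(set(labels)) < 2:
        raise FStatError("need at least two populations")
    comps = np.array([_locus_components(gt, labels, locus) for locus in gt.loci])
    return comps  # shape (L, 3)


def _ratios(comps: np.ndarray) -> tuple[float, float, float]:
    a, b, c = comps.sum(axis=0)
    total = a + b + c
    if total == 0:
        raise FStatError("all loci monomorphic: F-statistics undefined")
    theta = a / total
    F = 1.0 - c / total
    # at complete fixation there is no within-population variation: f is 0/0
    f = 1.0 - c / (b + c) if (b + c) != 0 else float("nan")
    return float(theta), float(f), float(F)


def weir_cockerham(gt: GenotypeTable, populations: list[str] | None = None) -> tuple[float, float, float]:
    """Point estimates (theta, f, F) over the given populations (default: all)."""
    return _ratios(_components_by_locus(gt, populations))


def bootstrap_ci(
    gt: GenotypeTable,
    populations: list[str] | None = None,
    n_boot: int = 1000,
    seed: int = 0,
    level: str = "all",
) -> FStatEstimates:
    """Point estimates plus percentile bootstrap CIs over loci.

    Loci are resampled with replacement ``n_boot`` times; with a fixed
    seed the intervals are reproducible. Requires at least two loci.
    """
    if len(gt.loci) < 2:
        raise FStatError("bootstrap over loci requires at least two loci")
    comps = _components_by_locus(gt, populations)
    theta, f, F = _ratios(comps)
    rng = np.random.default_rng(seed)
    L = comps.shape[0]
    thetas, fs = np.empty(n_boot), np.empty(n_boot)
    for i in range(n_boot):
        idx = rng.integers(0, L, size=L)
        t, fv, _ = _ratios(comps[idx])
        thetas[i], fs[i] = t, fv
    t_lo, t_hi = np.percentile(thetas, [2.5, 97.5])
    f_lo, f_hi = np.percentile(fs, [2.5, 97.5])
    return FStatEstimates(
        level=level, theta=theta, f=f, F=F,
        theta_ci=(float(t_lo), float(t_hi)), f_ci=(float(f_lo), float(f_hi)), n_boot=n_boot,
    )
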