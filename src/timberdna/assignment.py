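"""Leave-one-out self-assignment of individuals to populations and regions.

Scoring uses the Rannala-Mountain Bayesian criterion: each candidate
population's allele counts define a Dirichlet posterior (uniform prior,
pseudo-count 1/K per allele, K = alleles observed at the locus across all
populations), and an individual's genotype is scored by its
posterior-predictive (Polya urn) probability, multiplied across loci and
reported as log10. For self-assignment the individual's own two allele
copies are first removed from its own population's counts, so its
genotype never informs its own candidate score.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from math import log10

import numpy as np
import pandas as pd

from timberdna.allele_db import AlleleFreqDB, build_allele_db
from timberdna.genodata_io import MISSING, GenotypeTable

logger = logging.getLogger(__name__)


class AssignmentError(ValueError):
    pass


def _polya_genotype_prob(a: int, b: int, counts: dict[int, int], n_typed: int, k_locus: int) -> float:
    """Posterior-predictive probability of an unordered genotype (Polya urn).

    With prior pseudo-count 1/K per observed allele the total prior mass
    is 1, so the urn holds 2n + 1 'copies' before the first draw.
    """
    tau_a = counts.get(a, 0) + 1.0 / k_locus
    total = 2.0 * n_typed + 1.0
    if a == b:
        return tau_a * (tau_a + 1.0) / (total * (total + 1.0))
    tau_b = counts.get(b, 0) + 1.0 / k_locus
    return 2.0 * tau_a * tau_b / (total * (total + 1.0))


def rannala_mountain_loglik(
    profile: dict[str, tuple[int, int]],
    db: AlleleFreqDB,
    population: str,
    k_per_locus: dict[str, int] | None = None,
) -> float:
    """log10 posterior-predictive probability of a profile in one population.

    ``k_per_locus`` gives K, the number of alleles observed at each locus
    across all populations (defaults to the union over the database's
    groups). Loci absent from the database are skipped with a warning.
    """
    if k_per_locus is None:
        k_per_locus = global_allele_counts(db)
    g = db.groups[population]
    total = 0.0
    for locus, (a, b) in profile.items():
        if locus not in g.loci:
            logger.warning("locus %s absent from counts for %s; skipped", locus, population)
            continue
        lf = g.loci[locus]
        total += log10(_polya_genotype_prob(a, b, lf.counts, lf.n_typed, k_per_locus[locus]))
    return total


def global_allele_counts(db: AlleleFreqDB) -> dict[str, int]:
    """K per locus: distinct alleles observed at the locus across all groups."""
    out = {}
    for locus in db.loci:
        alleles = set()
        for g in db.groups.values():
            alleles.update(g.loci[locus].counts)
        out[locus] = max(len(alleles), 1)
    return out


@dataclass
class AssignmentSummary:
    per_sample: pd.DataFrame  # sample_id, true/assigned population and region, loglik
    population_accuracy: pd.DataFrame  # population, n, n_correct, pct_correct
    region_accuracy: pd.DataFrame  # region, n, n_correct, pct_correct
    mean_population_pct: float  # mean over populations, as printed in database reports
    mean_region_pct: float


def self_assignment(gt: GenotypeTable) -> AssignmentSummary:
    """Leave-one-out assignment of every individual to its maximum-likelihood population.

    Accuracy at the population level is the percentage of individuals
    assigned back to their own population; at the region level the
    percentage whose assigned population lies in their true region.
    Likelihood ties go to the first population in input order (warned).
    Individuals are scored on their non-missing loci only.
    """
    pops = gt.populations
    if len(pops) < 2:
        raise AssignmentError("self-assignment needs at least two populations")
    db = build_allele_db(gt, grouping="population")
    k_per_locus = global_allele_counts(db)
    pop_region = gt.population_of_region()
    for pop, g in db.groups.items():
        if g.n_individuals == 1:
            logger.warning("population %s has a single individual; it is scored on the prior alone", pop)

    rows = []
    for i in range(gt.n_samples):
        sid = gt.samples["sample_id"].iloc[i]
        true_pop = gt.samples["population"].iloc[i]
        profile = {}
        for locus in gt.loci:
            a, b = gt.genotypes[locus][i]
            if a != MISSING:
                profile[locus] = (int(a), int(b))
        own = db.groups[true_pop]
        # leave-one-out: strip this individual's alleles from its own counts
        removed = {}
        for locus, (a, b) in profile.items():
            lf = own.loci[locus]
            removed[locus] = dict(lf.counts), lf.n_typed
            lf.counts[a] -= 1
            lf.counts[b] -= 1
            for allele in {a, b}:
                if lf.counts[allele] == 0:
                    del lf.counts[allele]
            lf.n_typed -= 1
        scores = {pop: rannala_mountain_loglik(profile, db, pop, k_per_locus) for pop in pops}
        for locus, (counts, n_typed) in removed.items():
            own.loci[locus].counts = counts
            own.loci[locus].n_typed = n_typed
        best = max(scores.values())
        winners = [p for p in pops if scores[p] == best]
        if len(winners) > 1:
            logger.warning("likelihood tie for %s between %s; taking first in input order", sid, winners)
        assigned = winners[0]
        rows.append(
            {
                "sample_id": sid,
                "true_population": true_pop,
                "assigned_population": assigned,
                "true_region": pop_region.get(true_pop),
                "assigned_region": pop_region.get(assigned),
                "loglik_assigned": best,
                "correct_population": assigned == true_pop,
                "correct_region": pop_region.get(assigned) == pop_region.get(true_pop),
            }
        )
    per_sample = pd.DataFrame(rows)

    pop_rows = []
    for pop in pops:
        sub = per_sample[per_sample["true_population"] == pop]
        pop_rows.append(
            {
                "population": pop,
                "n": len(sub),
                "n_correct": int(sub["correct_population"].sum()),
                "pct_correct": 100.0 * sub["correct_population"].mean(),
            }
        )
    pop_acc = pd.DataFrame(pop_rows)

    region_rows = []
    regions = [r for r in dict.fromkeys(per_sample["true_region"]) if r is not None]
    for region in regions:
        sub = per_sample[per_sample["true_region"] == region]
        region_rows.append(
            {
                "region": region,
                "n": len(sub),
                "n_correct": int(sub["correct_region"].sum()),
                "pct_correct": 100.0 * sub["correct_region"].mean(),
            }
        )
    region_acc = pd.DataFrame(region_rows)
    mean_region = float(np.mean(region_acc["pct_correct"])) if len(region_acc) else float("nan")
    return AssignmentSummary(
        per_sample=per_sample,
        population_accuracy=pop_acc,
        region_accuracy=region_acc,
        mean_population_pct=float(np.mean(pop_acc["pct_correct"])),
        mean_region_pct=mean_region,
    )
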