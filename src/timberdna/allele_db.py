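"""Population- and region-level allele-frequency databases with a minimum-frequency floor.

The floor follows the NRC-II style rule 5/(2N): with fewer than five
copies of an allele expected in a database of N diploid individuals, its
raw frequency is replaced by 5/(2N) before any forensic profile-frequency
calculation. Raw frequencies (used for descriptive statistics) are always
retained alongside; floored frequencies are never renormalised, which is
conservative for match probabilities.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from timberdna.genodata_io import MISSING, GenotypeTable


class AlleleDBError(ValueError):
    pass


@dataclass
class LocusFreqs:
    """Allele-copy counts for one locus in one group."""

    counts: dict[int, int]
    n_typed: int  # individuals with a non-missing call at this locus

    def frequencies(self) -> dict[int, float]:
        total = 2 * self.n_typed
        if total == 0:
            return {}
        return {a: c / total for a, c in sorted(self.counts.items())}


@dataclass
class GroupFreqs:
    n_individuals: int
    loci: dict[str, LocusFreqs]


@dataclass
class AlleleFreqDB:
    """Per-group allele frequencies per locus, with sample sizes and an optional floor."""

    grouping: str  # population | region | combined | unknown
    groups: dict[str, GroupFreqs]
    loci: list[str]
    floor: float | dict[str, float] | None = field(default=None)

    @property
    def group_names(self) -> list[str]:
        return list(self.groups)

    def n_individuals(self, group: str) -> int:
        return self.groups[group].n_individuals

    def n_alleles(self, group: str, locus: str) -> int:
        return len(self.groups[group].loci[locus].counts)

    def raw_freq(self, group: str, locus: str) -> dict[int, float]:
        """Raw frequencies (descriptive statistics use these)."""
        return self.groups[group].loci[locus].frequencies()

    def floor_for(self, group: str) -> float | None:
        if self.floor is None:
            return None
        if isinstance(self.floor, dict):
            return self.floor[group]
        return self.floor

    def floored_freq(self, group: str, locus: str) -> dict[int, float]:
        """Frequencies with the minimum-frequency floor applied (forensic use)."""
        raw = self.raw_freq(group, locus)
        fl = self.floor_for(group)
        if fl is None:
            return raw
        return {a: max(p, fl) for a, p in raw.items()}

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for gname, g in self.groups.items():
            for locus in self.loci:
                lf = g.loci.get(locus)
                if lf is None or not lf.counts:
                    continue
                freqs = lf.frequencies()
                for allele in sorted(lf.counts):
                    rows.append(
                        {
                            "group": gname,
                            "locus": locus,
                            "allele": allele,
                            "count": lf.counts[allele],
                            "frequency": freqs[allele],
                            "n_individuals": g.n_individuals,
                        }
                    )
        return pd.DataFrame(rows)

    def equals(self, other: "AlleleFreqDB") -> bool:
        if self.loci != other.loci or set(self.groups) != set(other.groups):
            return False
        for g in self.groups:
            a, b = self.groups[g], other.groups[g]
            if a.n_individuals != b.n_individuals or set(a.loci) != set(b.loci):
                return False
            for locus in a.loci:
                if a.loci[locus].counts != b.loci[locus].counts:
                    return False
                if a.loci[locus].n_typed != b.loci[locus].n_typed:
                    return False
        return True


def _group_labels(gt: GenotypeTable, grouping: str) -> pd.Series:
    if grouping == "population":
        return gt.samples["population"]
    if grouping == "region":
        regions = gt.samples["region"]
        if regions.isna().any() or (regions == None).any():  # noqa: E711
            raise AlleleDBError("region grouping requested but some samples have no region label")
        return regions
    if grouping == "combined":
        return pd.Series(["combined"] * gt.n_samples, index=gt.samples.index)
    raise AlleleDBError(f"unknown grouping {grouping!r}")


def build_allele_db(gt: GenotypeTable, grouping: str = "population") -> AlleleFreqDB:
    """Count alleles per (group, locus): frequency = copies / (2 x non-missing individuals).

    Missing calls reduce the denominator of their locus only. A group with
    zero non-missing calls at a locus yields an empty frequency table for
    that locus (flagged by an empty ``counts`` dict).
    """
    if gt.n_samples == 0:
        raise AlleleDBError("empty genotype table")
    labels = _group_labels(gt, grouping)
    groups: dict[str, GroupFreqs] = {}
    for gname in dict.fromkeys(labels):
        mask = (labels == gname).to_numpy()
        locus_map = {}
        for locus in gt.loci:
            g = gt.genotypes[locus][mask]
            called = g[g[:, 0] != MISSING]
            alleles, counts = np.unique(called.ravel(), return_counts=True)
            locus_map[locus] = LocusFreqs(
                counts={int(a): int(c) for a, c in zip(alleles, counts)},
                n_typed=int(len(called)),
            )
        groups[str(gname)] = GroupFreqs(n_individuals=int(mask.sum()), loci=locus_map)
    return AlleleFreqDB(grouping=grouping, groups=groups, loci=list(gt.loci))


def min_allele_floor(n_individuals: int) -> float:
    """Minimum allele frequency 5/(2N), rounded half-up to 4 decimal places."""
    if n_individuals < 1:
        raise AlleleDBError("floor undefined for N < 1")
    raw = 5.0 / (2.0 * n_individuals)
    # round half-up (not banker's) to 4 decimals
    return math.floor(raw * 10_000 + 0.5) / 10_000


def apply_floor(db: AlleleFreqDB, floor: float | str = "auto") -> AlleleFreqDB:
    """Return a database whose forensic frequencies are floored.

    ``floor='auto'`` sets each group's floor to 5/(2N) of that group; a
    numeric floor applies uniformly. Raw frequencies remain available via
    :meth:`AlleleFreqDB.raw_freq`; flooring never lowers a frequency and
    is idempotent.
    """
    if floor == "auto":
        per_group = {g: min_allele_floor(db.groups[g].n_individuals) for g in db.groups}
        return replace(db, floor=per_group)
    floor = float(floor)
    if not (0.0 < floor < 1.0):
        raise AlleleDBError(f"floor must be in (0, 1), got {floor}")
    return replace(db, floor=floor)


def merge_groups(db: AlleleFreqDB, name: str, members: list[str]) -> AlleleFreqDB:
    """Pool member groups into a single group by summing allele counts."""
    locus_map: dict[str, LocusFreqs] = {}
    for locus in db.loci:
        counts: dict[int, int] = {}
        n_typed = 0
        for m in members:
            lf = db.groups[m].loci[locus]
            n_typed += lf.n_typed
            for a, c in lf.counts.items():
                counts[a] = counts.get(a, 0) + c
        locus_map[locus] = LocusFreqs(counts=counts, n_typed=n_typed)
    n = sum(db.groups[m].n_individuals for m in members)
    return AlleleFreqDB(
        grouping="merged",
        groups={name: GroupFreqs(n_individuals=n, loci=locus_map)},
        loci=list(db.loci),
    )
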