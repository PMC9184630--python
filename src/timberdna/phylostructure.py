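"""Nei's DA distance, UPGMA clustering and locus-bootstrap node support.

DA(X, Y) = 1 - (1/L) sum_loci sum_alleles sqrt(x_a * y_a): zero for
identical frequency vectors, one when allele sets are disjoint at every
locus. UPGMA is the arithmetic-average linkage with merge ties broken by
the lexicographically smallest label pair, giving a deterministic,
ultrametric tree. Node support is the percentage of locus-resampled
replicates whose UPGMA tree contains the same clade (loci, not
individuals, are the bootstrap unit).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np

from timberdna.allele_db import AlleleFreqDB, build_allele_db
from timberdna.genodata_io import GenotypeTable

logger = logging.getLogger(__name__)


class TreeError(ValueError):
    pass


@dataclass
class DistanceMatrix:
    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.labels), len(self.labels)):
            raise TreeError("distance matrix shape does not match labels")
        if not np.allclose(v, v.T) or not np.allclose(np.diag(v), 0.0):
            raise TreeError("distance matrix must be symmetric with a zero diagonal")
        self.values = v

    def get(self, a: str, b: str) -> float:
        i, j = self.labels.index(a), self.labels.index(b)
        return float(self.values[i, j])


@dataclass
class TreeNode:
    """Rooted ultrametric tree node (children empty for leaves)."""

    label: str | None = None
    height: float = 0.0
    children: list["TreeNode"] = field(default_factory=list)
    support: float | None = None

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> frozenset[str]:
        if self.is_leaf:
            return frozenset([self.label])
        return frozenset().union(*(c.leaves() for c in self.children))

    def clades(self) -> set[frozenset[str]]:
        """Leaf sets of all internal nodes below (and including) this one."""
        out: set[frozenset[str]] = set()
        if not self.is_leaf:
            out.add(self.leaves())
            for c in self.children:
                out |= c.clades()
        return out

    def newick(self, parent_height: float | None = None, with_support: bool = False) -> str:
        blen = "" if parent_height is None else f":{parent_height - self.height:.10g}"
        if self.is_leaf:
            return f"{self.label}{blen}"
        inner = ",".join(c.newick(self.height, with_support) for c in self.children)
        sup = ""
        if with_support and self.support is not None and parent_height is not None:
            sup = f"{self.support:g}"
        return f"({inner}){sup}{blen}"

    def to_newick(self, with_support: bool = False) -> str:
        return self.newick(None, with_support) + ";"


def nei_da(db: AlleleFreqDB) -> DistanceMatrix:
    """Pairwise Nei DA distances between the database's groups.

    A locus where either group has no data is dropped for that pair (with
    a warning); the average runs over the remaining loci.
    """
    labels = db.group_names
    if len(labels) < 2:
        raise TreeError("need at least two populations for a distance matrix")
    k = len(labels)
    values = np.zeros((k, k))
    for i, j in itertools.combinations(range(k), 2):
        shared = 0
        total = 0.0
        for locus in db.loci:
            x = db.raw_freq(labels[i], locus)
            y = db.raw_freq(labels[j], locus)
            if not x or not y:
                logger.warning("locus %s empty for %s/%s pair; dropped", locus, labels[i], labels[j])
                continue
            shared += 1
            total += sum(np.sqrt(x[a] * y[a]) for a in set(x) & set(y))
        if shared == 0:
            raise TreeError(f"no shared polymorphic loci between {labels[i]} and {labels[j]}")
        d = 1.0 - total / shared
        values[i, j] = values[j, i] = max(d, 0.0)
    return DistanceMatrix(labels=labels, values=values)


def upgma(dist: DistanceMatrix) -> TreeNode:
    """Average-linkage (UPGMA) tree; deterministic lexicographic tie-break."""
    if len(dist.labels) < 2:
        raise TreeError("UPGMA needs at least two taxa")
    nodes: dict[str, TreeNode] = {lab: TreeNode(label=lab) for lab in dist.labels}
    sizes = {lab: 1 for lab in dist.labels}
    # cluster keys: the lexicographically smallest member label
    d = {frozenset((a, b)): dist.get(a, b) for a, b in itertools.combinations(dist.labels, 2)}
    active = list(dist.labels)
    while len(active) > 1:
        best = min(
            (pair for pair in d if len(pair & set(active)) == 2),
            key=lambda pair: (d[pair], tuple(sorted(pair))),
        )
        a, b = sorted(best)
        height = d[best] / 2.0
        merged = TreeNode(height=height, children=[nodes[a], nodes[b]])
        key = a  # keep the smaller label as the cluster key
        na, nb = sizes[a], sizes[b]
        for other in active:
            if other in (a, b):
                continue
            dnew = (na * d[frozenset((a, other))] + nb * d[frozenset((b, other))]) / (na + nb)
            d[frozenset((key, other))] = dnew
        active = [x for x in active if x not in (a, b)] + [key]
        nodes[key] = merged
        sizes[key] = na + nb
    return nodes[active[0]]


def bootstrap_tree(
    gt: GenotypeTable, n_boot: int = 1000, seed: int = 0
) -> tuple[TreeNode, dict[frozenset[str], float]]:
    """UPGMA tree on Nei DA with % node support from locus bootstraps.

    Returns the original tree (internal nodes annotated with support) and
    the clade -> support map. Reproducible under a fixed seed.
    """
    if len(gt.loci) < 2:
        raise TreeError("bootstrap over loci requires at least two loci")
    db = build_allele_db(gt, grouping="population")
    tree = upgma(nei_da(db))
    target = tree.clades()
    hits = {clade: 0 for clade in target}
    rng = np.random.default_rng(seed)
    for _ in range(n_boot):
        loci = [gt.loci[i] for i in rng.integers(0, len(gt.loci), size=len(gt.loci))]
        boot_gt = GenotypeTable(
            samples=gt.samples.copy(),
            loci=[f"b{i}_{loc}" for i, loc in enumerate(loci)],
            genotypes={f"b{i}_{loc}": gt.genotypes[loc] for i, loc in enumerate(loci)},
        )
        boot_tree = upgma(nei_da(build_allele_db(boot_gt, grouping="population")))
        boot_clades = boot_tree.clades()
        for clade in target:
            if clade in boot_clades:
                hits[clade] += 1
    support = {clade: 100.0 * h / n_boot for clade, h in hits.items()}

    def annotate(node: TreeNode) -> None:
        if not node.is_leaf:
            node.support = support[node.leaves()]
            for c in node.children:
                annotate(c)

    annotate(tree)
    return tree, support
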