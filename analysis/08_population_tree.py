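"""UPGMA dendrogram of populations on Nei's DA with bootstrap support.

Loci are resampled 1000 times; node support is the percentage of
replicates reproducing each clade. With two genetic clusters present the
two region clades should dominate the topology.
"""

import argparse
from pathlib import Path

from timberdna import genodata_io as gio
from timberdna.phylostructure import bootstrap_tree


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--sim", type=Path, default=Path("results/sim"))
    ap.add_argument("--out", type=Path, default=Path("results/upgma_tree.nwk"))
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--boot", type=int, default=1000)
    args = ap.parse_args()

    gt = gio.read_genotype_table(args.sim / "genotypes.csv", dialect="genalex")
    tree, support = bootstrap_tree(gt, n_boot=args.boot, seed=args.seed)
    args.out.write_text(tree.to_newick(with_support=True) + "\n")
    for region in gt.regions:
        clade = frozenset(p for p in gt.populations if p.startswith(region))
        if clade in support:
            print(f"{region} clade support: {support[clade]:.0f}%")
    print(f"wrote -> {args.out}")


if __name__ == "__main__":
    main()
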