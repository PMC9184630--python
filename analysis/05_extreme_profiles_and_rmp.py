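"""Extreme multilocus profiles and random match probabilities per region.

The most common profile is heterozygous at every locus for the two
highest-frequency (floored) alleles; the rarest for the two lowest.
Profile frequencies use the subpopulation-cum-inbreeding model at the
region's estimated theta and f, and the reciprocal is reported as a
"1 in N" random match probability.
"""

import argparse
import json
from pathlib import Path

from timberdna import genodata_io as gio
from timberdna.allele_db import apply_floor, build_allele_db
from timberdna.fstatistics import weir_cockerham
from timberdna.profile_model import ProfileModelParams, extreme_profiles, random_match_probability


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--sim", type=Path, default=Path("results/sim"))
    ap.add_argument("--out", type=Path, default=Path("results/extreme_profiles.json"))
    args = ap.parse_args()

    gt = gio.read_genotype_table(args.sim / "genotypes.csv", dialect="genalex")
    out = {}
    for region in gt.regions:
        sub = gt.subset_region(region)
        theta, f, _ = weir_cockerham(sub)
        db = apply_floor(build_allele_db(sub, grouping="region"), "auto")
        params = ProfileModelParams(theta=max(theta, 0.0), f=max(f, 0.0))
        common, rare = extreme_profiles(db, region, params)
        out[region] = {
            "theta": round(theta, 4), "f": round(f, 4),
            "most_common_profile_freq": common, "rarest_profile_freq": rare,
            "rmp_most_common": random_match_probability(common),
            "rmp_rarest": random_match_probability(rare),
        }
        print(
            f"{region}: most common {common:.3g} ({out[region]['rmp_most_common']}); "
            f"rarest {rare:.3g} ({out[region]['rmp_rarest']})"
        )
    args.out.write_text(json.dumps(out, indent=1))
    print(f"wrote -> {args.out}")


if __name__ == "__main__":
    main()
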