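"""Packaged study metadata.

The shipped table lists the 44 natural sampling populations of the
reference study system (a Peninsular Malaysian dipterocarp timber tree),
their genetic-cluster region (A or B), coordinates, altitude and the
number of genotyped individuals per population.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd


def study_population_table() -> pd.DataFrame:
    """Return the published per-population sampling table.

    Columns: population, region, latitude, longitude, altitude_m, n_samples.
    """
    with resources.files("timberdna").joinpath("data/study_populations.csv").open() as fh:
        return pd.read_csv(fh)


def region_sample_sizes() -> dict[str, int]:
    """Total genotyped individuals per region, summed over member populations."""
    df = study_population_table()
    return df.groupby("region")["n_samples"].sum().to_dict()
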