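"""Database conservativeness (the d statistic) and upward calibration of theta.

For each reference individual the full-profile frequency is computed
twice: from its cognate population database (P_origin, with theta = 0 —
the cognate population *is* the subpopulation — and the regional
inbreeding estimate) and from the pooled regional database (P_combined,
with the calibration theta). The statistic

    d = log10(P_origin / P_combined)

is negative when the pooled database overstates the individual's profile
frequency, i.e. understates the weight of evidence — the conservative
direction for a defendant. A database is conservative when every
individual has d < 0; otherwise theta is stepped upward on a fixed grid
until it is. Calibration defaults to the conditional-match model
reading, under which P_combined grows with theta for homozygotes and for
heterozygotes away from the common-allele corner (1/p + 1/q > 5), so
multilocus P_combined is increasing in theta for realistic profiles and
the search terminates; a theta_max cap guards the remaining cases.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from timberdna.allele_db import AlleleFreqDB
from timberdna.genodata_io import MISSING, GenotypeTable
from timberdna.profile_model import (
    Profile,
    ProfileModelParams,
    ProfileModelError,
    log10_profile_frequency,
)

logger = logging.getLogger(__name__)


class ConservativenessError(ValueError):
    pass


@dataclass
class ConservativenessRecord:
    sample_id: str
    population: str
    log10_p_origin: float
    log10_p_combined: float

    @property
    def d(self) -> float:
        return self.log10_p_origin - self.log10_p_combined

    @property
    def conservative(self) -> bool:
        return self.d < 0.0


@dataclass
class CalibrationResult:
    theta_initial: float
    theta_adjusted: float
    step: float
    n_positive_d_at_initial: int
    converged: bool

    def __post_init__(self) -> None:
        self.theta_adjusted = round(self.theta_adjusted, 4)


def _single_group(db: AlleleFreqDB, group: str | None) -> str:
    if group is not None:
        return group
    if len(db.groups) != 1:
        raise ConservativenessError("database has several groups; name one explicitly")
    return next(iter(db.groups))


def d_statistic(
    profile: Profile,
    cognate_db: AlleleFreqDB,
    combined_db: AlleleFreqDB,
    params_origin: ProfileModelParams,
    params_combined: ProfileModelParams,
    cognate_group: str | None = None,
    combined_group: str | None = None,
    sample_id: str = "",
) -> ConservativenessRecord:
    """d = log10(P_origin) - log10(P_combined) for one complete profile."""
    cg = _single_group(cognate_db, cognate_group)
    rg = _single_group(combined_db, combined_group)
    lo = log10_profile_frequency(profile, cognate_db, cg, params_origin)
    lc = log10_profile_frequency(profile, combined_db, rg, params_combined)
    return ConservativenessRecord(
        sample_id=sample_id, population=cg, log10_p_origin=lo, log10_p_combined=lc
    )


def _complete_profiles(gt: GenotypeTable) -> list[tuple[str, str, Profile]]:
    out = []
    n_dropped = 0
    for i in range(gt.n_samples):
        profile: Profile = {}
        complete = True
        for locus in gt.loci:
            a, b = gt.genotypes[locus][i]
            if a == MISSING:
                complete = False
                break
            profile[locus] = (int(min(a, b)), int(max(a, b)))
        if complete:
            out.append((gt.samples["sample_id"].iloc[i], gt.samples["population"].iloc[i], profile))
        else:
            n_dropped += 1
    if n_dropped:
        logger.info("excluded %d individuals with incomplete profiles", n_dropped)
    if not out:
        raise ConservativenessError("no individual has a complete multilocus profile")
    return out


def evaluate_conservativeness(
    gt: GenotypeTable,
    pop_dbs: AlleleFreqDB,
    regional_db: AlleleFreqDB,
    params: ProfileModelParams,
    regional_group: str | None = None,
) -> tuple[list[ConservativenessRecord], dict]:
    """One ConservativenessRecord per complete individual, plus a summary.

    ``pop_dbs`` is the population-grouped (floored) database supplying
    P_origin (theta = 0, the regional f, same model reading as
    ``params``); ``regional_db`` supplies P_combined under ``params``.
    """
    rg = _single_group(regional_db, regional_group)
    params_origin = ProfileModelParams(theta=0.0, f=params.f, mode=params.mode)
    records = []
    for sid, pop, profile in _complete_profiles(gt):
        if pop not in pop_dbs.groups:
            raise ConservativenessError(f"no cognate database for population {pop!r}")
        lo = log10_profile_frequency(profile, pop_dbs, pop, params_origin)
        lc = log10_profile_frequency(profile, regional_db, rg, params)
        records.append(ConservativenessRecord(sid, pop, lo, lc))
    n_pos = sum(not r.conservative for r in records)
    summary = {
        "n": len(records),
        "n_nonconservative": n_pos,
        "fraction_nonconservative": n_pos / len(records),
        "theta": params.theta,
        "f": params.f,
        "mode": params.mode,
    }
    return records, summary


def records_frame(records: list[ConservativenessRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "sample_id": [r.sample_id for r in records],
            "population": [r.population for r in records],
            "log10_P_origin": [r.log10_p_origin for r in records],
            "log10_P_combined": [r.log10_p_combined for r in records],
            "d": [r.d for r in records],
            "conservative": [r.conservative for r in records],
        }
    )


def adjust_theta(
    gt: GenotypeTable,
    pop_dbs: AlleleFreqDB,
    regional_db: AlleleFreqDB,
    theta_init: float,
    f: float,
    step: float = 0.005,
    theta_max: float = 0.5,
    mode: str = "conditional-match",
    regional_group: str | None = None,
) -> CalibrationResult:
    """Smallest theta on the grid {theta_init + k*step} making every d negative.

    In conditional-match mode P_combined is non-decreasing in theta, so
    the first grid point with all d < 0 is the grid minimum. In
    unconditional mode (all-heterozygous profiles get *rarer* with theta)
    the search can fail to converge; it is then capped at ``theta_max``
    and reported as non-converged rather than looping.
    """
    if mode == "unconditional-frequency":
        logger.warning(
            "theta calibration in unconditional-frequency mode is not monotone; "
            "non-convergence will be reported instead of looping"
        )
    n_pos_initial: int | None = None
    theta = theta_init
    while theta <= theta_max + 1e-12:
        params = ProfileModelParams(theta=round(theta, 10), f=f, mode=mode)
        _, summary = evaluate_conservativeness(gt, pop_dbs, regional_db, params, regional_group)
        if n_pos_initial is None:
            n_pos_initial = summary["n_nonconservative"]
        if summary["n_nonconservative"] == 0:
            return CalibrationResult(
                theta_initial=theta_init,
                theta_adjusted=theta,
                step=step,
                n_positive_d_at_initial=n_pos_initial,
                converged=True,
            )
        theta += step
    return CalibrationResult(
        theta_initial=theta_init,
        theta_adjusted=theta_max,
        step=step,
        n_positive_d_at_initial=n_pos_initial or 0,
        converged=False,
    )
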