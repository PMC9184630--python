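"""Genotype and multilocus profile frequencies under the subpopulation-cum-inbreeding model.

Two standard readings of the theta-corrected genotype probability are
implemented and labelled explicitly:

``unconditional-frequency`` (default) — the expected frequency of the
genotype in a subpopulation with coancestry theta relative to the
database and within-population inbreeding f:

    P(A_i A_i) = f p_i + (1 - f) p_i [theta + (1 - theta) p_i]
    P(A_i A_j) = (1 - f) 2 p_i p_j (1 - theta)          (i != j)

These sum to 1 over the genotype space for every (theta, f).

``conditional-match`` — the classic Balding-Nichols match probabilities
(the probability of the genotype given one copy has already been seen in
the subpopulation), with f folded to zero:

    P(A_i A_i) = [2 theta + (1 - theta) p_i][3 theta + (1 - theta) p_i]
                 / [(1 + theta)(1 + 2 theta)]
    P(A_i A_j) = 2 [theta + (1 - theta) p_i][theta + (1 - theta) p_j]
                 / [(1 + theta)(1 + 2 theta)]

Conditional-match probabilities are non-decreasing in theta for every
homozygote, and for heterozygotes whenever 1/p_i + 1/p_j > 5 (i.e.
unless both alleles are common; p = q = 0.5 is the classic exception,
where the probability 0.5(1+theta)/(1+2theta) decreases). Full-profile
products over realistic multi-allelic loci are dominated by rarer
alleles and increase with theta in practice, which is what makes upward
calibration of theta conservative.

A multilocus profile frequency is the product of genotype frequencies
across loci, computed from *floored* allele frequencies.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import log10

from timberdna.allele_db import AlleleFreqDB

MODES = ("unconditional-frequency", "conditional-match")


class ProfileModelError(ValueError):
    pass


@dataclass(frozen=True)
class ProfileModelParams:
    """Coancestry theta, inbreeding f, and which genotype-probability reading to use."""

    theta: float = 0.0
    f: float = 0.0
    mode: str = "unconditional-frequency"

    def __post_init__(self) -> None:
        if not (0.0 <= self.theta < 1.0):
            raise ProfileModelError(f"theta must be in [0, 1), got {self.theta}")
        if not (0.0 <= self.f < 1.0):
            raise ProfileModelError(f"f must be in [0, 1), got {self.f}")
        if self.mode not in MODES:
            raise ProfileModelError(f"mode must be one of {MODES}, got {self.mode!r}")


Genotype = tuple[int, int]
Profile = dict[str, Genotype]


def genotype_frequency(genotype: Genotype, locus_freqs: dict[int, float], params: ProfileModelParams) -> float:
    """Probability of an unordered allele pair under the chosen model reading."""
    a, b = sorted(genotype)
    for allele in (a, b):
        if allele not in locus_freqs:
            raise ProfileModelError(
                f"allele {allele} absent from the frequency table; apply a minimum-frequency "
                "floor (see allele_db.apply_floor) so unseen alleles get the floor frequency"
            )
    t, f = params.theta, params.f
    p, q = locus_freqs[a], locus_freqs[b]
    if params.mode == "unconditional-frequency":
        if a == b:
            return f * p + (1.0 - f) * p * (t + (1.0 - t) * p)
        return (1.0 - f) * 2.0 * p * q * (1.0 - t)
    # conditional-match (Balding-Nichols / NRC-II 4.10), f folded to 0
    denom = (1.0 + t) * (1.0 + 2.0 * t)
    if a == b:
        return (2.0 * t + (1.0 - t) * p) * (3.0 * t + (1.0 - t) * p) / denom
    return 2.0 * (t + (1.0 - t) * p) * (t + (1.0 - t) * q) / denom


def profile_frequency(profile: Profile, db: AlleleFreqDB, group: str, params: ProfileModelParams) -> float:
    """Product of genotype frequencies across all database loci (floored frequencies).

    The profile must be complete: a locus in the database but not in the
    profile is an error (no imputation).
    """
    missing = [loc for loc in db.loci if loc not in profile]
    if missing:
        raise ProfileModelError(f"profile incomplete at loci {missing}; cannot compute a full-profile frequency")
    prob = 1.0
    for locus in db.loci:
        prob *= genotype_frequency(profile[locus], db.floored_freq(group, locus), params)
    return prob


def tie_break_extremes(locus_freqs: dict[int, float]) -> tuple[Genotype, Genotype]:
    """The two most-common and two rarest alleles as heterozygous pairs.

    Frequency ties are broken towards the smaller fragment size, so the
    selection is deterministic.
    """
    if len(locus_freqs) < 2:
        raise ProfileModelError("extreme profiles need at least two alleles per locus")
    by_common = sorted(locus_freqs, key=lambda a: (-locus_freqs[a], a))
    by_rare = sorted(locus_freqs, key=lambda a: (locus_freqs[a], a))
    common_pair = tuple(sorted(by_common[:2]))
    rare_pair = tuple(sorted(by_rare[:2]))
    return common_pair, rare_pair


def extreme_profiles(db: AlleleFreqDB, group: str, params: ProfileModelParams) -> tuple[float, float]:
    """(most-common, rarest) full-profile frequencies for a database group.

    The most common profile is heterozygous at every locus for the two
    highest-frequency alleles (after flooring); the rarest for the two
    lowest-frequency alleles.
    """
    common_profile: Profile = {}
    rare_profile: Profile = {}
    for locus in db.loci:
        freqs = db.floored_freq(group, locus)
        common_pair, rare_pair = tie_break_extremes(freqs)
        common_profile[locus] = common_pair
        rare_profile[locus] = rare_pair
    return (
        profile_frequency(common_profile, db, group, params),
        profile_frequency(rare_profile, db, group, params),
    )


_SCALE_NAMES = [
    (1e15, "quadrillion"),
    (1e12, "trillion"),
    (1e9, "billion"),
    (1e6, "million"),
    (1e3, "thousand"),
]


def random_match_probability(profile_freq: float) -> str:
    """Format the reciprocal of a profile frequency as a '1 in N' statement.

    The reciprocal is expressed to three significant figures on the
    largest named scale it reaches, e.g. 2.69e-7 -> '1 in 3.72 million'.
    """
    if profile_freq <= 0.0:
        raise ProfileModelError("profile frequency must be positive")
    value = 1.0 / profile_freq
    if value >= 1000.0 * _SCALE_NAMES[0][0]:  # beyond named scales: plain scientific
        return f"1 in {value:.3g}"
    for scale, name in _SCALE_NAMES:
        x = value / scale
        if float(f"{x:.3g}") >= 1.0:  # accept once x rounds to >= 1 on this scale
            return f"1 in {x:.3g} {name}"
    return f"1 in {value:.3g}"


def log10_profile_frequency(profile: Profile, db: AlleleFreqDB, group: str, params: ProfileModelParams) -> float:
    """log10 of the profile frequency, summed per locus to avoid underflow."""
    total = 0.0
    missing = [loc for loc in db.loci if loc not in profile]
    if missing:
        raise ProfileModelError(f"profile incomplete at loci {missing}")
    for locus in db.loci:
        total += log10(genotype_frequency(profile[locus], db.floored_freq(group, locus), params))
    return total
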