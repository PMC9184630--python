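"""Synthetic SSR genotype tables and cpDNA alignments with hierarchical structure.

The SSR generator follows the Balding–Nichols F-model: ancestral allele
frequencies per locus are drawn from a symmetric Dirichlet; regional
frequencies from a Dirichlet centred on the ancestral vector with
concentration (1-theta)/theta (so the among-region coancestry is theta in
expectation); population frequencies likewise around their region. Within
a population an individual is autozygous with probability f (one allele
drawn and duplicated), otherwise its two alleles are independent draws —
reproducing a within-population inbreeding coefficient of f.

The cpDNA generator builds a reference spacer sequence per marker and
derives haplotypes from it by single-carrier base substitutions and gap
runs (deletions), one dominant haplotype per region plus rare endemic
variants, returning truth labels for recovery testing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from timberdna.genodata_io import MISSING, Alignment, GenotypeTable


class SimulationError(ValueError):
    pass


@dataclass
class SimConfig:
    """Parameters of the hierarchical SSR genotype simulator.

    Defaults emulate the study design this package models: two regions of
    nested populations, among-population coancestry around 0.05,
    within-population inbreeding around 0.08, and ten unlinked
    multi-allelic loci with allele counts in the observed 7-31 range.
    """

    n_regions: int = 2
    pops_per_region: int = 6
    n_per_pop: int = 32
    n_loci: int = 10
    alleles_per_locus: int | list[int] = 12
    theta_region: float = 0.05
    theta_pop: float = 0.05
    f_inbreed: float = 0.08
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("theta_region", "theta_pop", "f_inbreed", "missing_rate"):
            v = getattr(self, name)
            if not (0.0 <= v < 1.0):
                raise SimulationError(f"{name} must be in [0, 1), got {v}")
        for name in ("n_regions", "pops_per_region", "n_per_pop", "n_loci"):
            if getattr(self, name) < 1:
                raise SimulationError(f"{name} must be >= 1")
        if isinstance(self.alleles_per_locus, int):
            self.alleles_per_locus = [self.alleles_per_locus] * self.n_loci
        if len(self.alleles_per_locus) != self.n_loci:
            raise SimulationError("alleles_per_locus list must have n_loci entries")
        if any(k < 1 for k in self.alleles_per_locus):
            raise SimulationError("each locus needs >= 1 allele")


def _balding_nichols(rng: np.random.Generator, parent: np.ndarray, theta: float) -> np.ndarray:
    """Draw offspring frequencies around ``parent`` with coancestry ``theta``."""
    if theta == 0.0:
        return parent.copy()
    conc = (1.0 - theta) / theta * parent
    # Dirichlet with a zero concentration component degenerates; clip to tiny
    conc = np.clip(conc, 1e-12, None)
    return rng.dirichlet(conc)


def simulate_hierarchical_ssr(cfg: SimConfig) -> GenotypeTable:
    """Simulate a two-level (region -> population) structured SSR genotype table.

    Deterministic under a fixed ``cfg.seed``. Allele labels are plausible
    dinucleotide fragment sizes (100 + 2k bp).
    """
    rng = np.random.default_rng(cfg.seed)
    loci = [f"L{j + 1:02d}" for j in range(cfg.n_loci)]
    ancestral = [rng.dirichlet(np.ones(k)) for k in cfg.alleles_per_locus]

    sample_ids, pops, regions = [], [], []
    pop_freqs: dict[str, list[np.ndarray]] = {}
    for r in range(cfg.n_regions):
        region_name = f"Region{chr(ord('A') + r)}" if cfg.n_regions <= 26 else f"Region{r + 1}"
        region_f = [_balding_nichols(rng, p, cfg.theta_region) for p in ancestral]
        for p in range(cfg.pops_per_region):
            pop_name = f"{region_name}-P{p + 1:02d}"
            pop_freqs[pop_name] = [_balding_nichols(rng, q, cfg.theta_pop) for q in region_f]
            for i in range(cfg.n_per_pop):
                sample_ids.append(f"{pop_name}-S{i + 1:03d}")
                pops.append(pop_name)
                regions.append(region_name)

    n = len(sample_ids)
    genotypes = {locus: np.empty((n, 2), dtype=np.int64) for locus in loci}
    labels = [100 + 2 * np.arange(k) for k in cfg.alleles_per_locus]
    row = 0
    for pop_name in dict.fromkeys(pops):
        m = pops.count(pop_name)
        auto = rng.random((m, cfg.n_loci)) < cfg.f_inbreed
        for j, locus in enumerate(loci):
            freqs = pop_freqs[pop_name][j]
            k = len(freqs)
            draws = rng.choice(k, size=(m, 2), p=freqs)
            draws[auto[:, j], 1] = draws[auto[:, j], 0]
            genotypes[locus][row : row + m] = labels[j][draws]
        row += m

    if cfg.missing_rate > 0.0:
        miss = rng.random((n, cfg.n_loci)) < cfg.missing_rate
        for j, locus in enumerate(loci):
            genotypes[locus][miss[:, j]] = MISSING

    samples = pd.DataFrame({"sample_id": sample_ids, "population": pops, "region": regions})
    return GenotypeTable(samples=samples, loci=loci, genotypes=genotypes)


# ---------------------------------------------------------------------------
# chloroplast haplotypes


@dataclass
class CpSimConfig:
    """Parameters of the cpDNA haplotype simulator.

    ``substitution_sites`` and ``deletion_events`` are the total numbers of
    variable events across the concatenated markers; defaults mirror the
    four intergenic spacers (573/487/500/593 bp) and the 21-substitution,
    7-deletion variability the package's haplotype caller is built around.
    """

    n_markers: int = 4
    marker_lengths: list[int] = field(default_factory=lambda: [573, 487, 500, 593])
    n_haplotypes_per_region: int = 3
    substitution_sites: int = 21
    deletion_events: int = 7
    rare_haplotype_rate: float = 0.03
    samples_per_region: int = 40
    pops_per_region: int = 2
    max_deletion_length: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.marker_lengths) != self.n_markers:
            raise SimulationError("marker_lengths must have n_markers entries")
        if not (0.0 <= self.rare_haplotype_rate < 1.0):
            raise SimulationError("rare_haplotype_rate must be in [0, 1)")


def _place_events(rng, marker_lengths, n_events, max_run):
    """Non-overlapping event anchor positions, each run fitting inside one marker."""
    bounds = np.cumsum([0] + list(marker_lengths))
    total = bounds[-1]
    margin = max_run + 2
    taken: list[tuple[int, int]] = []
    positions = []
    attempts = 0
    while len(positions) < n_events:
        attempts += 1
        if attempts > 20_000:
            raise SimulationError("cannot place variable sites: markers too short for requested events")
        pos = int(rng.integers(1, total - max_run - 1))
        m = int(np.searchsorted(bounds, pos, side="right") - 1)
        if pos + max_run >= bounds[m + 1]:  # run must not span a marker boundary
            continue
        if any(pos < e + margin and s < pos + margin for s, e in taken):
            continue
        taken.append((pos, pos + max_run))
        positions.append(pos)
    return sorted(positions)


def simulate_cpdna(cfg: CpSimConfig, regions: list[str] | None = None):
    """Simulate per-marker cpDNA alignments with region-dominant haplotypes.

    Returns ``(alignments, metadata, truth)``: one :class:`Alignment` per
    marker, a sample metadata frame (sample_id, population, region) and a
    dict mapping sample_id to its true haplotype index. Each region has
    one dominant haplotype; the remaining ``n_haplotypes_per_region - 1``
    are rare endemics confined to a single population and emitted at
    ``rare_haplotype_rate`` (always at least one copy). Haplotypes differ
    by single-carrier substitutions and gap runs, so every simulated event
    is recoverable as exactly one variable site.
    """
    if regions is None:
        regions = ["Region A", "Region B"]
    rng = np.random.default_rng(cfg.seed)
    k = len(regions) * cfg.n_haplotypes_per_region
    n_events = cfg.substitution_sites + cfg.deletion_events
    if n_events < k:
        raise SimulationError(
            f"{n_events} variable events cannot distinguish {k} haplotypes; "
            "need substitution_sites + deletion_events >= total haplotypes"
        )

    total_len = sum(cfg.marker_lengths)
    reference = rng.choice(list("ACGT"), size=total_len)
    positions = _place_events(rng, cfg.marker_lengths, n_events, cfg.max_deletion_length)
    kinds = np.array(["sub"] * cfg.substitution_sites + ["del"] * cfg.deletion_events)
    rng.shuffle(kinds)

    # carrier haplotype for each event: cycle over the non-reference haplotypes
    # (haplotype 0 is the reference / dominant of the first region)
    events = []  # (kind, pos, run_len or alt_base, carrier)
    for j, (pos, kind) in enumerate(zip(positions, kinds)):
        carrier = 1 + j % (k - 1) if k > 1 else 0
        if kind == "sub":
            alt = rng.choice([b for b in "ACGT" if b != reference[pos]])
            events.append(("sub", pos, alt, carrier))
        else:
            run = int(rng.integers(1, cfg.max_deletion_length + 1))
            events.append(("del", pos, run, carrier))

    hap_seqs = []
    for h in range(k):
        seq = reference.copy()
        for kind, pos, payload, carrier in events:
            if carrier != h:
                continue
            if kind == "sub":
                seq[pos] = payload
            else:
                seq[pos : pos + payload] = "-"
        hap_seqs.append("".join(seq))

    sample_ids, pops, regs, truth = [], [], [], {}
    counter = 0
    for r, region in enumerate(regions):
        hap_ids = list(range(r * cfg.n_haplotypes_per_region, (r + 1) * cfg.n_haplotypes_per_region))
        dominant, rares = hap_ids[0], hap_ids[1:]
        n_rare_each = max(1, int(round(cfg.rare_haplotype_rate * cfg.samples_per_region)))
        pop_names = [f"{region}-P{p + 1}" for p in range(cfg.pops_per_region)]
        assignments = []
        for h in rares:
            endemic_pop = pop_names[int(rng.integers(len(pop_names)))]
            assignments.extend([(h, endemic_pop)] * n_rare_each)
        n_dom = cfg.samples_per_region - len(assignments)
        if n_dom < 1:
            raise SimulationError("samples_per_region too small for the requested rare haplotypes")
        for i in range(n_dom):
            assignments.append((dominant, pop_names[i % len(pop_names)]))
        for h, pop in assignments:
            counter += 1
            sid = f"cp{counter:04d}"
            sample_ids.append(sid)
            pops.append(pop)
            regs.append(region)
            truth[sid] = h

    bounds = np.cumsum([0] + list(cfg.marker_lengths))
    alignments = []
    for m in range(cfg.n_markers):
        recs = {
            sid: hap_seqs[truth[sid]][bounds[m] : bounds[m + 1]] for sid in sample_ids
        }
        alignments.append(Alignment(marker_name=f"marker{m + 1}", records=recs))
    metadata = pd.DataFrame({"sample_id": sample_ids, "population": pops, "region": regs})
    return alignments, metadata, truth
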