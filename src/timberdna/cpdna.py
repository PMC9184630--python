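"""Chloroplast haplotype database: variable sites, haplotype calling, origin inference.

Variable sites come in two kinds: substitution columns (at least two
distinct non-gap, non-N states among samples) and deletion events, where
a maximal run of gap columns shared identically by a subset of samples
counts as ONE event regardless of its length; overlapping but unequal gap
runs are separate events. A haplotype is the tuple of states across all
variable sites; identical tuples collapse and are named H1..Hk in
descending frequency (ties by first observation). Mapping haplotypes to
the regions where they were observed yields the origin-inference lookup:
a haplotype seen in exactly one region is diagnostic for it.

Coordinates are 0-based half-open internally and 1-based in reports.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from timberdna.genodata_io import Alignment, FormatError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class VariableSite:
    column: int  # 0-based start column in the concatenated alignment
    kind: str  # "substitution" | "deletion"
    states: tuple[str, ...]  # observed states (bases, or "-"/"+" for deletions)
    end: int  # exclusive end column (column + 1 for substitutions)

    @property
    def report_position(self) -> str:
        """1-based position (or inclusive range) for human-readable reports."""
        if self.end - self.column == 1:
            return str(self.column + 1)
        return f"{self.column + 1}-{self.end}"


@dataclass
class HaplotypeTable:
    """Unique haplotypes, their per-population counts and region diagnostics."""

    haplotypes: dict[str, tuple[str, ...]]  # name -> state tuple, H1.. by descending count
    assignments: dict[str, str]  # sample_id -> haplotype name
    unresolved: list[str]  # sample_ids with ambiguous missing states
    sites: list[VariableSite]
    population_counts: pd.DataFrame = field(default=None)  # haplotype x population
    regions_of: dict[str, set[str]] = field(default_factory=dict)

    @property
    def n_haplotypes(self) -> int:
        return len(self.haplotypes)

    def counts(self) -> dict[str, int]:
        out = {name: 0 for name in self.haplotypes}
        for name in self.assignments.values():
            out[name] += 1
        return out


def concatenate_alignments(alns: list[Alignment]) -> tuple[Alignment, list[int]]:
    """Column-wise concatenation across markers sharing one sample set.

    Returns the combined alignment and the start offsets of each marker
    (marker boundaries).
    """
    if not alns:
        raise FormatError("no alignments to concatenate")
    ids = set(alns[0].records)
    for aln in alns[1:]:
        if set(aln.records) != ids:
            only = sorted(set(aln.records) ^ ids)
            raise FormatError(f"sample sets differ across markers; unmatched ids: {only}")
    order = list(alns[0].records)
    records = {sid: "".join(aln.records[sid] for aln in alns) for sid in order}
    boundaries = []
    offset = 0
    for aln in alns:
        boundaries.append(offset)
        offset += aln.length
    name = "+".join(a.marker_name for a in alns)
    return Alignment(marker_name=name, records=records), boundaries


def _gap_runs(seq: str) -> list[tuple[int, int]]:
    runs = []
    start = None
    for i, ch in enumerate(seq):
        if ch == "-" and start is None:
            start = i
        elif ch != "-" and start is not None:
            runs.append((start, i))
            start = None
    if start is not None:
        runs.append((start, len(seq)))
    return runs


def find_variable_sites(aln: Alignment) -> list[VariableSite]:
    """Detect substitution columns and deletion events in an alignment.

    Columns whose only variation involves N are not variable; a column
    inside a polymorphic gap run is accounted for by its deletion event,
    not as a substitution.
    """
    seqs = list(aln.records.values())
    if len(seqs) < 2:
        return []
    sites: list[VariableSite] = []
    n = len(seqs)
    # deletion events: distinct maximal gap runs present in some but not all samples
    run_carriers: dict[tuple[int, int], int] = {}
    for seq in seqs:
        for run in _gap_runs(seq):
            run_carriers[run] = run_carriers.get(run, 0) + 1
    for (start, end), carriers in sorted(run_carriers.items()):
        if 0 < carriers < n:
            sites.append(VariableSite(column=start, kind="deletion", states=("+", "-"), end=end))
    for col in range(aln.length):
        observed = {seq[col] for seq in seqs} - {"N", "-"}
        if len(observed) >= 2:
            sites.append(
                VariableSite(column=col, kind="substitution", states=tuple(sorted(observed)), end=col + 1)
            )
    sites.sort(key=lambda s: (s.column, s.kind))
    return sites


def _sample_states(seq: str, sites: list[VariableSite]) -> tuple[str | None, ...]:
    """Per-site states for one sample; None marks a missing (N) state."""
    states: list[str | None] = []
    for site in sites:
        if site.kind == "substitution":
            ch = seq[site.column]
            states.append(None if ch == "N" else ch)
        else:
            window = seq[site.column : site.end]
            if "N" in window:
                states.append(None)
            elif set(window) == {"-"} and (site.column, site.end) in _run_lookup(seq):
                states.append("-")
            else:
                states.append("+")
    return tuple(states)


def _run_lookup(seq: str) -> set[tuple[int, int]]:
    return set(_gap_runs(seq))


def call_haplotypes(
    aln: Alignment, sites: list[VariableSite], metadata: pd.DataFrame | None = None
) -> HaplotypeTable:
    """Collapse samples into haplotypes over the variable sites.

    Samples with missing (N) states join an existing haplotype only when
    exactly one is compatible; otherwise they are flagged unresolved.
    ``metadata`` (sample_id, population, region) adds per-population
    counts and the haplotype -> regions diagnostic map.
    """
    complete: dict[tuple, list[str]] = {}
    partial: list[tuple[str, tuple]] = []
    for sid, seq in aln.records.items():
        states = _sample_states(seq, sites)
        if any(s is None for s in states):
            partial.append((sid, states))
        else:
            complete.setdefault(states, []).append(sid)

    unresolved = []
    for sid, states in partial:
        compatible = [
            key
            for key in complete
            if all(s is None or s == k for s, k in zip(states, key))
        ]
        if len(compatible) == 1:
            complete[compatible[0]].append(sid)
        else:
            unresolved.append(sid)
            logger.warning("sample %s has ambiguous missing states; unresolved", sid)

    # name H1..Hk by descending count, ties by first observation order
    order_of_first = {key: i for i, key in enumerate(complete)}
    ranked = sorted(complete, key=lambda key: (-len(complete[key]), order_of_first[key]))
    haplotypes = {f"H{i + 1}": key for i, key in enumerate(ranked)}
    assignments = {sid: name for name, key in haplotypes.items() for sid in complete[key]}

    pop_counts = None
    regions_of: dict[str, set[str]] = {}
    if metadata is not None:
        meta = metadata.set_index("sample_id")
        rows = []
        for sid, name in assignments.items():
            rows.append(
                {
                    "haplotype": name,
                    "population": meta.loc[sid, "population"],
                    "region": meta.loc[sid, "region"] if "region" in meta.columns else None,
                }
            )
        df = pd.DataFrame(rows)
        pop_counts = df.pivot_table(
            index="haplotype", columns="population", aggfunc="size", fill_value=0
        )
        for name, sub in df.groupby("haplotype"):
            regions_of[name] = set(r for r in sub["region"] if r is not None)
    return HaplotypeTable(
        haplotypes=haplotypes,
        assignments=assignments,
        unresolved=unresolved,
        sites=list(sites),
        population_counts=pop_counts,
        regions_of=regions_of,
    )


def infer_region(query_haplotype: str | tuple, table: HaplotypeTable) -> dict:
    """Regional origin of a query haplotype from the database's diagnostics.

    The query may be a haplotype name (e.g. 'H3') or a state tuple.
    Status is 'diagnostic' (one region), 'shared' (several) or 'unknown'.
    """
    if not table.regions_of:
        raise FormatError("haplotype table was built without region metadata")
    name = None
    if isinstance(query_haplotype, str) and query_haplotype in table.haplotypes:
        name = query_haplotype
    else:
        key = tuple(query_haplotype)
        for hname, states in table.haplotypes.items():
            if states == key:
                name = hname
                break
    if name is None:
        return {"status": "unknown", "regions": []}
    regions = sorted(table.regions_of.get(name, set()))
    if len(regions) == 1:
        return {"status": "diagnostic", "regions": regions, "haplotype": name}
    return {"status": "shared", "regions": regions, "haplotype": name}
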