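"""Readers, writers and the core data model for SSR genotypes and cpDNA alignments.

SSR alleles are fragment sizes in base pairs and are stored as integers
throughout; a genotype is an unordered pair of alleles. Missing calls are
``0/0`` or blank cells on disk (GenAlEx convention) and :data:`MISSING`
(-1) in memory — a locus call is either both-present or both-missing.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

MISSING = -1

ALIGNMENT_ALPHABET = set("ACGT-N")


class FormatError(ValueError):
    """Raised when an input file violates the expected dialect."""


@dataclass
class GenotypeTable:
    """Diploid multilocus SSR genotypes with population and region labels.

    Parameters
    ----------
    samples
        DataFrame with columns ``sample_id``, ``population``, ``region``
        (region entries may be ``None`` when no region map is known).
    loci
        Ordered locus names, identical for every sample.
    genotypes
        Mapping locus -> ``(n_samples, 2)`` integer array of allele sizes,
        with :data:`MISSING` in both slots for a missing call.
    """

    samples: pd.DataFrame
    loci: list[str]
    genotypes: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        required = {"sample_id", "population", "region"}
        if not required.issubset(self.samples.columns):
            missing = required - set(self.samples.columns)
            raise FormatError(f"sample table lacks columns: {sorted(missing)}")
        ids = self.samples["sample_id"]
        if ids.duplicated().any():
            dupes = ids[ids.duplicated()].tolist()
            raise FormatError(f"duplicate sample_id: {dupes}")
        n = len(self.samples)
        for locus in self.loci:
            g = np.asarray(self.genotypes[locus])
            if g.shape != (n, 2):
                raise FormatError(f"locus {locus}: genotype array shape {g.shape} != ({n}, 2)")
            half = (g == MISSING).sum(axis=1) == 1
            if half.any():
                raise FormatError(f"locus {locus}: half-missing genotype at rows {np.where(half)[0].tolist()}")
            self.genotypes[locus] = g.astype(np.int64)
        # region labels must partition populations, not split them
        reg = self.samples.groupby("population", sort=False)["region"].nunique(dropna=False)
        if (reg > 1).any():
            bad = reg[reg > 1].index.tolist()
            raise FormatError(f"populations mapped to multiple regions: {bad}")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def populations(self) -> list[str]:
        return list(dict.fromkeys(self.samples["population"]))

    @property
    def regions(self) -> list[str]:
        vals = [r for r in dict.fromkeys(self.samples["region"]) if r is not None]
        return vals

    def population_of_region(self) -> dict[str, str]:
        """population -> region map (region ``None`` when unset)."""
        return dict(zip(self.samples["population"], self.samples["region"]))

    def subset(self, mask: np.ndarray) -> "GenotypeTable":
        """Row subset by boolean mask or integer index array (order-preserving)."""
        mask = np.asarray(mask)
        if mask.dtype != bool:
            idx = np.zeros(self.n_samples, dtype=bool)  # validate bounds
            idx[mask] = True
            samples = self.samples.iloc[mask].reset_index(drop=True)
            genos = {loc: self.genotypes[loc][mask] for loc in self.loci}
            return GenotypeTable(samples=samples, loci=list(self.loci), genotypes=genos)
        samples = self.samples.loc[mask].reset_index(drop=True)
        genos = {loc: self.genotypes[loc][mask] for loc in self.loci}
        return GenotypeTable(samples=samples, loci=list(self.loci), genotypes=genos)

    def subset_populations(self, pops: Iterable[str]) -> "GenotypeTable":
        keep = set(pops)
        return self.subset(self.samples["population"].isin(keep).to_numpy())

    def subset_region(self, region: str) -> "GenotypeTable":
        return self.subset((self.samples["region"] == region).to_numpy())

    def with_regions(self, region_map: Mapping[str, str]) -> "GenotypeTable":
        """Return a copy with regions assigned from a population -> region map."""
        unknown = set(self.populations) - set(region_map)
        if unknown:
            raise FormatError(f"populations missing from region map: {sorted(unknown)}")
        samples = self.samples.copy()
        samples["region"] = samples["population"].map(region_map)
        return GenotypeTable(samples=samples, loci=list(self.loci), genotypes=dict(self.genotypes))

    def equals(self, other: "GenotypeTable") -> bool:
        if self.loci != other.loci or not self.samples.equals(other.samples):
            return False
        return all(np.array_equal(self.genotypes[l], other.genotypes[l]) for l in self.loci)


@dataclass
class Alignment:
    """An aligned set of sequences over {A, C, G, T, -, N} for one marker."""

    marker_name: str
    records: dict[str, str]
    length: int = field(default=0)

    def __post_init__(self) -> None:
        lengths = {sid: len(seq) for sid, seq in self.records.items()}
        if lengths:
            distinct = set(lengths.values())
            if len(distinct) > 1:
                ragged = [sid for sid, n in lengths.items() if n != max(distinct)]
                raise FormatError(
                    f"alignment {self.marker_name}: ragged lengths {sorted(distinct)} (e.g. record {ragged[0]})"
                )
            self.length = distinct.pop()
        normed = {}
        for sid, seq in self.records.items():
            seq = seq.upper()
            bad = set(seq) - ALIGNMENT_ALPHABET
            if bad:
                raise FormatError(f"record {sid}: illegal characters {sorted(bad)}")
            normed[sid] = seq
        self.records = normed

    @property
    def sample_ids(self) -> list[str]:
        return list(self.records)

    def column(self, i: int) -> list[str]:
        return [seq[i] for seq in self.records.values()]


# ---------------------------------------------------------------------------
# genotype tables


def _parse_allele(token: str) -> int:
    token = token.strip()
    if token == "" or token == "0":
        return MISSING
    try:
        return int(token)
    except ValueError as exc:
        raise FormatError(f"allele {token!r} is not an integer fragment size") from exc


def _finalise_genotypes(rows, loci, region_map):
    sample_ids, populations, regions, geno_rows = rows
    samples = pd.DataFrame({"sample_id": sample_ids, "population": populations, "region": regions})
    genotypes = {}
    for j, locus in enumerate(loci):
        arr = np.array([[r[2 * j], r[2 * j + 1]] for r in geno_rows], dtype=np.int64)
        # normalise half-missing (one 0 slot) to fully missing
        any_missing = (arr == MISSING).any(axis=1)
        arr[any_missing] = MISSING
        genotypes[locus] = arr
    gt = GenotypeTable(samples=samples, loci=list(loci), genotypes=genotypes)
    if region_map is not None:
        gt = gt.with_regions(region_map)
    return gt


def read_genotype_table(
    path: str | Path,
    dialect: str = "genalex",
    region_map: Mapping[str, str] | None = None,
) -> GenotypeTable:
    """Read a genotype CSV in the long or GenAlEx-like wide dialect.

    ``genalex`` (wide): header ``sample_id,population[,region]`` followed by
    two columns per locus (the locus name on the first of each pair; the
    second may repeat it or be blank). ``long``: one row per sample x locus
    with columns ``sample_id,population[,region],locus,allele1,allele2``.

    Missing genotypes are encoded as 0 or blank cells; a half-missing pair
    is normalised to fully missing. When ``region_map`` is given it
    overrides any region column; absent both, regions are left unset.
    """
    path = Path(path)
    if dialect == "long":
        df = pd.read_csv(path, dtype={"sample_id": str, "population": str})
        needed = {"sample_id", "population", "locus", "allele1", "allele2"}
        if not needed.issubset(df.columns):
            raise FormatError(f"long dialect requires columns {sorted(needed)}")
        if "region" not in df.columns:
            df["region"] = None
        loci = list(dict.fromkeys(df["locus"]))
        wide = df.pivot_table(
            index="sample_id", columns="locus", values=["allele1", "allele2"], aggfunc="first", sort=False
        )
        meta = df.drop_duplicates("sample_id").set_index("sample_id")
        sample_ids = list(dict.fromkeys(df["sample_id"]))
        geno_rows = []
        for sid in sample_ids:
            row = []
            for locus in loci:
                a1 = wide.loc[sid, ("allele1", locus)]
                a2 = wide.loc[sid, ("allele2", locus)]
                row.extend([_coerce_allele(a1), _coerce_allele(a2)])
            geno_rows.append(row)
        rows = (
            sample_ids,
            [meta.loc[s, "population"] for s in sample_ids],
            [meta.loc[s, "region"] if pd.notna(meta.loc[s, "region"]) else None for s in sample_ids],
            geno_rows,
        )
        return _finalise_genotypes(rows, loci, region_map)
    if dialect not in {"genalex", "genalex-like", "wide"}:
        raise FormatError(f"unknown dialect {dialect!r}")
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration as exc:
            raise FormatError("empty genotype file") from exc
        header = [h.strip() for h in header]
        meta_cols = ["sample_id", "population"]
        if len(header) > 2 and header[2] == "region":
            meta_cols.append("region")
        k = len(meta_cols)
        allele_cols = header[k:]
        if len(allele_cols) % 2 != 0:
            raise FormatError(f"odd number of allele columns ({len(allele_cols)}); need two per locus")
        loci = []
        for j in range(0, len(allele_cols), 2):
            name = allele_cols[j] or allele_cols[j + 1]
            if not name:
                raise FormatError(f"unnamed locus pair at columns {k + j}-{k + j + 1}")
            loci.append(name)
        if len(set(loci)) != len(loci):
            raise FormatError(f"duplicate locus names in header: {loci}")
        sample_ids, populations, regions, geno_rows = [], [], [], []
        for line in reader:
            if not any(cell.strip() for cell in line):
                continue
            line = line + [""] * (len(header) - len(line))
            sample_ids.append(line[0].strip())
            populations.append(line[1].strip())
            regions.append(line[2].strip() or None if "region" in meta_cols else None)
            geno_rows.append([_parse_allele(tok) for tok in line[k : k + 2 * len(loci)]])
    return _finalise_genotypes((sample_ids, populations, regions, geno_rows), loci, region_map)


def _coerce_allele(value) -> int:
    if pd.isna(value):
        return MISSING
    v = int(value)
    return MISSING if v == 0 else v


def write_genotype_table(gt: GenotypeTable, path: str | Path, dialect: str = "genalex") -> None:
    """Write a genotype table in the long or GenAlEx-like wide dialect."""
    path = Path(path)
    has_region = any(r is not None for r in gt.samples["region"])
    if dialect == "long":
        rows = []
        for i, rec in gt.samples.iterrows():
            for locus in gt.loci:
                a1, a2 = gt.genotypes[locus][i]
                rows.append(
                    {
                        "sample_id": rec["sample_id"],
                        "population": rec["population"],
                        "region": rec["region"],
                        "locus": locus,
                        "allele1": 0 if a1 == MISSING else int(a1),
                        "allele2": 0 if a2 == MISSING else int(a2),
                    }
                )
        df = pd.DataFrame(rows)
        if not has_region:
            df = df.drop(columns=["region"])
        df.to_csv(path, index=False)
        return
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        meta = ["sample_id", "population"] + (["region"] if has_region else [])
        header = meta + [name for locus in gt.loci for name in (locus, locus)]
        writer.writerow(header)
        for i, rec in gt.samples.iterrows():
            row = [rec["sample_id"], rec["population"]] + ([rec["region"] or ""] if has_region else [])
            for locus in gt.loci:
                a1, a2 = gt.genotypes[locus][i]
                row.extend(["0" if a1 == MISSING else str(int(a1)), "0" if a2 == MISSING else str(int(a2))])
            writer.writerow(row)


# ---------------------------------------------------------------------------
# allele-frequency tables


def write_allele_freq_table(db, path: str | Path) -> None:
    """Serialise an :class:`~timberdna.allele_db.AlleleFreqDB` to CSV.

    Columns: group, locus, allele, count, frequency, n_individuals. Raw
    (un-floored) frequencies are written; they sum to 1 per (group, locus).
    """
    rows = db.to_frame()
    if rows.empty:
        raise FormatError("refusing to write an empty allele-frequency database")
    rows.to_csv(path, index=False)


def read_allele_freq_table(path: str | Path):
    """Read an allele-frequency CSV back into an AlleleFreqDB."""
    from timberdna.allele_db import AlleleFreqDB, GroupFreqs, LocusFreqs

    df = pd.read_csv(path, dtype={"group": str, "locus": str})
    needed = {"group", "locus", "allele", "frequency", "n_individuals"}
    if not needed.issubset(df.columns):
        raise FormatError(f"allele-frequency table requires columns {sorted(needed)}")
    groups: dict[str, GroupFreqs] = {}
    loci = list(dict.fromkeys(df["locus"]))
    for gname, gdf in df.groupby("group", sort=False):
        locus_map = {}
        for locus, ldf in gdf.groupby("locus", sort=False):
            if "count" in ldf.columns and ldf["count"].notna().all():
                counts = {int(a): int(c) for a, c in zip(ldf["allele"], ldf["count"])}
            else:  # frequency-only tables (e.g. published supplements)
                n2 = 2 * int(ldf["n_individuals"].iloc[0])
                counts = {int(a): int(round(f * n2)) for a, f in zip(ldf["allele"], ldf["frequency"])}
            locus_map[locus] = LocusFreqs(counts=counts, n_typed=sum(counts.values()) // 2)
        groups[str(gname)] = GroupFreqs(n_individuals=int(gdf["n_individuals"].iloc[0]), loci=locus_map)
    return AlleleFreqDB(grouping="unknown", groups=groups, loci=loci)


# ---------------------------------------------------------------------------
# alignments


def read_aligned_fasta(path: str | Path, marker_name: str | None = None) -> Alignment:
    """Read an aligned FASTA; lowercase is normalised to uppercase.

    Raises :class:`FormatError` naming the offending record when sequence
    lengths are ragged.
    """
    path = Path(path)
    records = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            raise FormatError(f"duplicate sequence id {rec.id}")
        records[rec.id] = str(rec.seq).upper()
    if not records:
        raise FormatError(f"no FASTA records in {path}")
    return Alignment(marker_name=marker_name or path.stem, records=records)


def write_aligned_fasta(aln: Alignment, path: str | Path) -> None:
    recs = [SeqRecord(Seq(seq), id=sid, description="") for sid, seq in aln.records.items()]
    SeqIO.write(recs, str(path), "fasta")
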