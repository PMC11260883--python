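"""Haplotype collapsing and construction of the two parallel dataset views.

Barcoding studies traditionally remove redundant haplotypes before computing
distances; keeping them weights common haplotypes by their sampling frequency.
This module builds both units of analysis from one input alignment:

* the **unique-haplotype view** (per-species haplotype count N_H), and
* the **all-sequences view** (per-species sequence count N_S, redundancy
  retained),

and applies the inclusion filters (minimum N_H, minimum N_S, minimum species
per genus) that decide which species and genera enter the gap analyses.

Two sequences are the *same haplotype* when they have zero countable
differences: no alignment column where both carry an unambiguous nucleotide
and the nucleotides differ.  Missing data make this relation non-transitive
("ACGT" matches "ACGN" matches "ACGA", but "ACGT" differs from "ACGA"), so
groups are closed transitively via union-find, with a warning when a merged
group contains a pair that genuinely differs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .distances import encode
from .seq_io import GenusDataset, SeqRecord

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Haplotype:
    """One collapsed haplotype: representative sequence plus its members."""

    haplotype_id: str
    representative: SeqRecord
    member_records: tuple[SeqRecord, ...]

    @property
    def multiplicity(self) -> int:
        return len(self.member_records)

    @property
    def member_ids(self) -> tuple[str, ...]:
        return tuple(r.id for r in self.member_records)


@dataclass
class HaplotypeTable:
    """Per-species unique haplotypes with multiplicities for one genus."""

    genus: str
    alignment_length: int
    entries: dict[str, list[Haplotype]] = field(default_factory=dict)

    def n_h(self, species: str) -> int:
        """Number of unique haplotypes for a species."""
        return len(self.entries.get(species, []))

    def n_s(self, species: str) -> int:
        """Total number of sequences for a species (redundancy included)."""
        return sum(h.multiplicity for h in self.entries.get(species, []))

    @property
    def species(self) -> list[str]:
        return list(self.entries)

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            {
                "species": sp,
                "haplotype_id": h.haplotype_id,
                "member_ids": ",".join(h.member_ids),
                "multiplicity": h.multiplicity,
            }
            for sp, haps in self.entries.items()
            for h in haps
        ]
        return pd.DataFrame(rows, columns=["species", "haplotype_id", "member_ids", "multiplicity"])

    def write_tsv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False)


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[max(ri, rj)] = min(ri, rj)


def countable_differences(a: str, b: str) -> int:
    """Sites where both sequences are unambiguous {A,C,G,T} and differ."""
    ca, cb = encode(a), encode(b)
    return int(((ca != 255) & (cb != 255) & (ca != cb)).sum())


def collapse_haplotypes(ds: GenusDataset) -> HaplotypeTable:
    """Group each species' sequences into unique haplotypes.

    Grouping uses the zero-countable-differences relation closed transitively.
    The representative of a group is its longest sequence by non-missing
    characters, ties broken by lexicographically smallest id, so output is
    deterministic and order-independent.
    """
    table = HaplotypeTable(genus=ds.genus, alignment_length=ds.alignment_length)
    for sp, recs in ds.by_species().items():
        recs = sorted(recs, key=lambda r: r.id)
        n = len(recs)
        codes = [encode(r.residues) for r in recs]
        uf = _UnionFind(n)
        diff = np.zeros((n, n), dtype=bool)
        for i in range(n):
            for j in range(i + 1, n):
                d = int(((codes[i] != 255) & (codes[j] != 255) & (codes[i] != codes[j])).sum())
                diff[i, j] = diff[j, i] = d > 0
                if d == 0:
                    uf.union(i, j)
        groups: dict[int, list[int]] = {}
        for i in range(n):
            groups.setdefault(uf.find(i), []).append(i)
        haps: list[Haplotype] = []
        for members in groups.values():
            if any(diff[i, j] for i in members for j in members if i < j):
                logger.warning(
                    "%s / %s: transitive merge chained non-identical sequences %s "
                    "through missing data",
                    ds.genus, sp, [recs[i].id for i in members],
                )
            rep = min(members, key=lambda i: (-recs[i].n_present, recs[i].id))
            haps.append(
                Haplotype(
                    haplotype_id=recs[rep].id,
                    representative=recs[rep],
                    member_records=tuple(recs[i] for i in sorted(members)),
                )
            )
        haps.sort(key=lambda h: h.haplotype_id)
        table.entries[sp] = haps
    return table


@dataclass(frozen=True)
class InclusionConfig:
    """Sample-size filters a species/genus must meet to enter gap analyses."""

    min_n_h: int = 6
    min_n_s: int = 12
    min_species_per_genus: int = 4

    def __post_init__(self) -> None:
        if min(self.min_n_h, self.min_n_s, self.min_species_per_genus) < 1:
            raise ValueError("all inclusion thresholds must be >= 1")


@dataclass
class DatasetViews:
    """The two parallel views built from per-genus haplotype tables.

    ``nh``: genus -> dataset of unique haplotypes for species with
    n_h >= min_n_h.  ``ns``: genus -> dataset of all sequences for species
    with n_s >= min_n_s.  Genera with too few qualifying species are absent
    from that view (a genus may qualify in one view only).
    """

    nh: dict[str, GenusDataset] = field(default_factory=dict)
    ns: dict[str, GenusDataset] = field(default_factory=dict)


def build_datasets(tables: dict[str, HaplotypeTable], cfg: InclusionConfig = InclusionConfig()) -> DatasetViews:
    """Apply inclusion filters and materialize the two dataset views."""
    views = DatasetViews()
    for genus, table in tables.items():
        nh_records: list[SeqRecord] = []
        ns_records: list[SeqRecord] = []
        nh_species = 0
        ns_species = 0
        for sp in table.species:
            haps = table.entries[sp]
            if table.n_h(sp) >= cfg.min_n_h:
                nh_species += 1
                nh_records.extend(h.representative for h in haps)
            if table.n_s(sp) >= cfg.min_n_s:
                ns_species += 1
                for h in haps:
                    ns_records.extend(h.member_records)
        if nh_species >= cfg.min_species_per_genus:
            views.nh[genus] = GenusDataset(genus, tuple(nh_records), table.alignment_length)
        if ns_species >= cfg.min_species_per_genus:
            views.ns[genus] = GenusDataset(genus, tuple(ns_records), table.alignment_length)
    if not views.nh and not views.ns:
        logger.warning("no genus satisfied the inclusion thresholds %s", cfg)
    return views
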