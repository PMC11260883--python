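"""Five-category comparison of recognized species against delimited clusters.

Each recognized (currently named) species is compared with the clusters of a
delimited partition and classified as exactly one of:

* ``perfect_taxonomy`` — its members form exactly one cluster, alone;
* ``pure_undersplit`` — split across >= 2 clusters, each containing only its
  own members (naming new species would reconcile taxonomy);
* ``impure_undersplit`` — split across >= 2 clusters, at least one of which
  also holds members of another species;
* ``pure_oversplit`` — pooled with other species into one cluster, where
  every pooled species lies wholly in that cluster (synonymy would
  reconcile);
* ``impure_oversplit`` — pooled into one cluster with a species that also
  has members elsewhere.

"Pure" means a simple taxonomic change (new name or synonymy) could reconcile
the discrepancy; "impure" means it could not.  A species that is both split
and sharing clusters is an impure undersplit — the split takes precedence.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import pandas as pd

from .delimitation import Partition
from .seq_io import MetadataError

CATEGORIES = (
    "perfect_taxonomy",
    "pure_undersplit",
    "impure_undersplit",
    "pure_oversplit",
    "impure_oversplit",
)

#: Table-style short codes for each category
CATEGORY_CODES = {
    "perfect_taxonomy": "PT",
    "pure_undersplit": "PU",
    "impure_undersplit": "IU",
    "pure_oversplit": "PO",
    "impure_oversplit": "IO",
}


@dataclass(frozen=True)
class ConcordanceRecord:
    species: str
    category: str
    clusters_spanned: int
    cohabitant_species: tuple[str, ...]  # other species sharing a cluster


def classify_species(
    recognized: Mapping[str, frozenset[str] | set[str]], part: Partition
) -> list[ConcordanceRecord]:
    """Classify every recognized species against a delimited partition.

    ``recognized`` maps species label -> its member sequence ids; the species
    must partition the id set covered by ``part``.
    """
    all_members = set()
    for ids in recognized.values():
        overlap = all_members & set(ids)
        if overlap:
            raise MetadataError(f"ids assigned to multiple recognized species: {sorted(overlap)}")
        all_members |= set(ids)
    part_ids = set(part.assignment)
    if all_members != part_ids:
        raise MetadataError(
            f"recognized species and partition cover different ids: "
            f"only-recognized {sorted(all_members - part_ids)}, "
            f"only-partition {sorted(part_ids - all_members)}"
        )

    clusters = part.clusters()
    records: list[ConcordanceRecord] = []
    for sp, ids in recognized.items():
        members = set(ids)
        spanned = {part.assignment[i] for i in members}
        cohabitants = sorted(
            {
                other
                for other, other_ids in recognized.items()
                if other != sp
                and any(part.assignment[i] in spanned for i in other_ids)
            }
        )
        if len(spanned) == 1:
            (c,) = spanned
            cluster_ids = clusters[c]
            if cluster_ids == frozenset(members):
                cat = "perfect_taxonomy"
            else:
                # pooled with at least one other species in cluster c
                pure = all(
                    set(recognized[other]) <= cluster_ids for other in cohabitants
                )
                cat = "pure_oversplit" if pure else "impure_oversplit"
        else:
            exclusive = all(clusters[c] <= members for c in spanned)
            cat = "pure_undersplit" if exclusive else "impure_undersplit"
        records.append(
            ConcordanceRecord(
                species=sp,
                category=cat,
                clusters_spanned=len(spanned),
                cohabitant_species=tuple(cohabitants),
            )
        )
    return records


def recognized_from_labels(labels: Mapping[str, str]) -> dict[str, frozenset[str]]:
    """Invert an id -> species map into species -> member-id sets."""
    out: dict[str, set[str]] = {}
    for id_, sp in labels.items():
        out.setdefault(sp, set()).add(id_)
    return {sp: frozenset(v) for sp, v in out.items()}


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


@dataclass(frozen=True)
class ConcordanceSummary:
    """Category counts and integer percentages, plus the delimitation ratio."""

    counts: dict[str, int]
    percentages: dict[str, int]
    n_recognized: int
    n_delimited: int

    @property
    def delimited_ratio(self) -> float:
        """Delimited-to-recognized species count ratio, 1 decimal."""
        return round(self.n_delimited / self.n_recognized, 1)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "category": CATEGORY_CODES[c],
                    "count": self.counts[c],
                    "percent": self.percentages[c],
                }
                for c in CATEGORIES
            ]
        )


def summarize_concordance(
    records: list[ConcordanceRecord], part: Partition
) -> ConcordanceSummary:
    """Count records per category with percentages rounded half-up to integers."""
    if not records:
        raise ValueError("no concordance records")
    counts = {c: 0 for c in CATEGORIES}
    for r in records:
        counts[r.category] += 1
    total = len(records)
    percentages = {c: _round_half_up(100.0 * counts[c] / total) for c in CATEGORIES}
    return ConcordanceSummary(
        counts=counts,
        percentages=percentages,
        n_recognized=total,
        n_delimited=part.n_clusters,
    )


def records_dataframe(records: list[ConcordanceRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "species": r.species,
                "category": r.category,
                "clusters_spanned": r.clusters_spanned,
                "cohabitants": ",".join(r.cohabitant_species),
            }
            for r in records
        ]
    )


def write_concordance(
    records: list[ConcordanceRecord], summary: ConcordanceSummary, outdir: str | Path
) -> None:
    outdir = Path(outdir)
    records_dataframe(records).to_csv(outdir / "concordance.tsv", sep="\t", index=False)
    summary.to_dataframe().to_csv(outdir / "concordance_summary.tsv", sep="\t", index=False)
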