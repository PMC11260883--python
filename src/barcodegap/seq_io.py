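"""Reading, validation, trimming and ORF quality control of aligned barcode data.

A dataset here is always a single-genus alignment: every analysis downstream
(haplotype collapsing, distances, gap detection, delimitation) operates within
a genus, so sequences from different genera are never mixed in one
:class:`GenusDataset`.

Missing characters for coverage purposes are ``-``, ``N`` and ``?``.  IUPAC
partial ambiguities (R, Y, S, W, K, M, B, D, H, V) count as *present* for
column coverage and sequence length, but are excluded from site comparisons in
the distance module (pairwise deletion over strict {A, C, G, T}).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Data import CodonTable

logger = logging.getLogger(__name__)

#: characters treated as missing data (gaps / undetermined / unknown)
MISSING_CHARS = frozenset("-N?")
#: unambiguous nucleotides; only these count as comparable sites
UNAMBIGUOUS = frozenset("ACGT")
#: full accepted residue alphabet (IUPAC nucleotide codes + missing)
ALPHABET = frozenset("ACGTURYSWKMBDHVN-?")


class AlignmentError(ValueError):
    """Raised for ragged alignments or length mismatches."""


class MetadataError(ValueError):
    """Raised when sequence ids and the metadata table disagree."""


class DuplicateIdError(ValueError):
    """Raised when a sequence id occurs more than once."""


@dataclass(frozen=True)
class SeqRecord:
    """One aligned sequence with its taxonomic labels.

    ``species`` may be an undescribed-species placeholder (e.g. ``"sp. C"``);
    it is treated as an ordinary species label throughout.
    """

    id: str
    genus: str
    species: str
    residues: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence id must be non-empty")
        bad = set(self.residues.upper()) - ALPHABET
        if bad:
            raise ValueError(f"{self.id}: invalid residue characters {sorted(bad)}")

    @property
    def n_present(self) -> int:
        """Number of non-missing characters (ambiguity codes count as present)."""
        return sum(c not in MISSING_CHARS for c in self.residues)


@dataclass(frozen=True)
class GenusDataset:
    """An aligned set of sequences from one genus, with species labels."""

    genus: str
    records: tuple[SeqRecord, ...]
    alignment_length: int

    def __post_init__(self) -> None:
        if not self.records:
            raise ValueError("GenusDataset requires at least one record")
        ids = [r.id for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise DuplicateIdError(f"duplicate sequence ids: {dupes}")
        genera = {r.genus for r in self.records}
        if genera != {self.genus}:
            raise MetadataError(
                f"dataset genus {self.genus!r} but records carry {sorted(genera)}"
            )
        for r in self.records:
            if len(r.residues) != self.alignment_length:
                raise AlignmentError(
                    f"{r.id}: length {len(r.residues)} != alignment length "
                    f"{self.alignment_length}"
                )

    def __len__(self) -> int:
        return len(self.records)

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    @property
    def species_labels(self) -> dict[str, str]:
        """Map sequence id -> species label."""
        return {r.id: r.species for r in self.records}

    @property
    def species(self) -> list[str]:
        """Distinct species labels in first-appearance order."""
        seen: dict[str, None] = {}
        for r in self.records:
            seen.setdefault(r.species, None)
        return list(seen)

    def subset(self, ids: Iterable[str]) -> "GenusDataset":
        """New dataset restricted to ``ids`` (original record order kept)."""
        wanted = set(ids)
        recs = tuple(r for r in self.records if r.id in wanted)
        missing = wanted - {r.id for r in recs}
        if missing:
            raise MetadataError(f"ids not in dataset: {sorted(missing)}")
        return GenusDataset(self.genus, recs, self.alignment_length)

    def by_species(self) -> dict[str, list[SeqRecord]]:
        out: dict[str, list[SeqRecord]] = {}
        for r in self.records:
            out.setdefault(r.species, []).append(r)
        return out


def read_alignment(fasta_path: str | Path, metadata_path: str | Path) -> GenusDataset:
    """Read an aligned FASTA plus a tab-separated metadata table.

    The metadata table must have columns ``id``, ``genus`` and ``species`` and
    cover every FASTA id exactly once.  All sequences must share one length
    and one genus label.
    """
    meta = pd.read_csv(metadata_path, sep="\t", dtype=str)
    required = {"id", "genus", "species"}
    if not required.issubset(meta.columns):
        raise MetadataError(
            f"metadata must have columns {sorted(required)}, got {list(meta.columns)}"
        )
    if meta["id"].duplicated().any():
        dupes = sorted(meta.loc[meta["id"].duplicated(), "id"])
        raise DuplicateIdError(f"duplicate ids in metadata: {dupes}")
    lookup: Mapping[str, tuple[str, str]] = {
        row.id: (row.genus, row.species) for row in meta.itertuples()
    }

    records: list[SeqRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        if rec.id in seen:
            raise DuplicateIdError(f"duplicate id in FASTA: {rec.id}")
        seen.add(rec.id)
        if rec.id not in lookup:
            raise MetadataError(f"FASTA id {rec.id!r} missing from metadata")
        genus, species = lookup[rec.id]
        records.append(
            SeqRecord(id=rec.id, genus=genus, species=species, residues=str(rec.seq).upper())
        )
    if not records:
        raise AlignmentError(f"no sequences in {fasta_path}")

    lengths = {len(r.residues) for r in records}
    if len(lengths) != 1:
        raise AlignmentError(f"ragged alignment: sequence lengths {sorted(lengths)}")
    genera = {r.genus for r in records}
    if len(genera) != 1:
        raise MetadataError(f"mixed genera in one dataset: {sorted(genera)}")

    return GenusDataset(genus=records[0].genus, records=tuple(records), alignment_length=lengths.pop())


def write_alignment(ds: GenusDataset, fasta_path: str | Path, metadata_path: str | Path) -> None:
    """Write a dataset back to FASTA + metadata TSV (inverse of read_alignment)."""
    with open(fasta_path, "w") as fh:
        for r in ds.records:
            fh.write(f">{r.id}\n{r.residues}\n")
    pd.DataFrame(
        {"id": [r.id for r in ds.records],
         "genus": [r.genus for r in ds.records],
         "species": [r.species for r in ds.records]}
    ).to_csv(metadata_path, sep="\t", index=False)


@dataclass(frozen=True)
class TrimResult:
    """Outcome of end-trimming: the trimmed dataset plus what was removed."""

    dataset: GenusDataset
    leading_removed: int
    trailing_removed: int
    dropped_ids: tuple[str, ...]


def trim_alignment(
    ds: GenusDataset,
    min_col_coverage: float = 0.9,
    min_seq_bp: int = 200,
) -> TrimResult:
    """Trim poorly covered alignment ends and drop too-short sequences.

    Leading and trailing columns whose fraction of non-missing characters is
    below ``min_col_coverage`` are removed; internal columns are never touched.
    Sequences left with fewer than ``min_seq_bp`` non-missing characters are
    then dropped.  Retained characters are never altered, so the operation is
    idempotent.
    """
    if not (0 < min_col_coverage <= 1):
        raise ValueError("min_col_coverage must be in (0, 1]")
    if min_seq_bp < 1:
        raise ValueError("min_seq_bp must be >= 1")

    n = len(ds.records)
    L = ds.alignment_length
    coverage = [
        sum(r.residues[j] not in MISSING_CHARS for r in ds.records) / n for j in range(L)
    ]
    start = 0
    while start < L and coverage[start] < min_col_coverage:
        start += 1
    end = L
    while end > start and coverage[end - 1] < min_col_coverage:
        end -= 1

    kept: list[SeqRecord] = []
    dropped: list[str] = []
    for r in ds.records:
        trimmed = replace(r, residues=r.residues[start:end])
        if trimmed.n_present >= min_seq_bp:
            kept.append(trimmed)
        else:
            dropped.append(r.id)
    if not kept:
        raise AlignmentError(
            "trimming removed every sequence "
            f"(min_col_coverage={min_col_coverage}, min_seq_bp={min_seq_bp})"
        )
    if start or end != L or dropped:
        logger.info(
            "trim %s: removed %d leading + %d trailing columns, dropped %d sequences",
            ds.genus, start, L - end, len(dropped),
        )
    out = GenusDataset(ds.genus, tuple(kept), end - start)
    return TrimResult(out, start, L - end, tuple(dropped))


@dataclass(frozen=True)
class OrfReport:
    """Result of an open-reading-frame check on one sequence."""

    id: str
    passed: bool
    first_stop: int | None  # codon index (0-based, within the frame) of first stop
    codons_checked: int


def check_orf(rec: SeqRecord, code: int = 5, frame: int = 0) -> OrfReport:
    """Check that a coding sequence has no internal stop codon.

    ``code`` is an NCBI genetic-code table id; the default 5 is the
    invertebrate mitochondrial code appropriate for arthropod COI.  Codons
    containing missing or ambiguous characters are skipped rather than counted
    as stops, since their translation is undetermined.
    """
    if frame not in (0, 1, 2):
        raise ValueError("frame must be 0, 1 or 2")
    try:
        table = CodonTable.unambiguous_dna_by_id[code]
    except KeyError as exc:
        raise ValueError(f"unknown genetic code id: {code}") from exc
    stops = set(table.stop_codons)

    seq = rec.residues.upper()[frame:]
    n_unambig = sum(c in UNAMBIGUOUS for c in seq)
    if n_unambig < 3:
        raise ValueError(f"{rec.id}: fewer than 3 unambiguous characters in frame {frame}")

    first_stop: int | None = None
    checked = 0
    for k in range(len(seq) // 3):
        codon = seq[3 * k : 3 * k + 3]
        if any(c not in UNAMBIGUOUS for c in codon):
            continue
        checked += 1
        if codon in stops:
            first_stop = k
            break
    return OrfReport(id=rec.id, passed=first_stop is None, first_stop=first_stop, codons_checked=checked)
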