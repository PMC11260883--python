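"""Kimura two-parameter (K2P) pairwise distances with pairwise deletion.

The K2P model distinguishes transitions (A<->G, C<->T) from transversions and
assumes uniform rates among sites.  For a sequence pair, with P and Q the
proportions of comparable sites showing a transition and a transversion
respectively, the distance in substitutions/site is

    d = -1/2 * ln((1 - 2P - Q) * sqrt(1 - 2Q))

Comparable sites are columns where *both* sequences carry an unambiguous
nucleotide (strict {A, C, G, T}); gaps, N, ? and IUPAC partial ambiguities are
excluded pair by pair (pairwise deletion).  Saturated pairs, where a log
argument is non-positive and the formula is undefined, are masked as
inapplicable rather than assigned an arbitrary large value; downstream
statistics skip them.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .seq_io import AlignmentError, GenusDataset, MetadataError

logger = logging.getLogger(__name__)

# nucleotide codes: A=0, G=1, C=2, T=3 so that a transition keeps the
# purine/pyrimidine bit (code // 2) fixed; everything else is incomparable
_CODE = np.full(256, 255, dtype=np.uint8)
for _c, _v in zip("AGCT", range(4)):
    _CODE[ord(_c)] = _v
    _CODE[ord(_c.lower())] = _v


def encode(residues: str) -> np.ndarray:
    """Encode residues as uint8: A=0, G=1, C=2, T=3, anything else 255."""
    return _CODE[np.frombuffer(residues.encode("ascii"), dtype=np.uint8)]


class K2PResult(NamedTuple):
    distance: float  # nan when inapplicable
    p: float  # transition proportion
    q: float  # transversion proportion
    sites: int  # comparable sites
    applicable: bool


def k2p_distance(a: str | np.ndarray, b: str | np.ndarray) -> K2PResult:
    """K2P distance between two aligned sequences under pairwise deletion.

    Returns distance nan / applicable False when there are no comparable
    sites or the correction is undefined (saturation).
    """
    ca = encode(a) if isinstance(a, str) else a
    cb = encode(b) if isinstance(b, str) else b
    if ca.shape != cb.shape:
        raise AlignmentError(f"length mismatch: {ca.size} vs {cb.size}")
    both = (ca != 255) & (cb != 255)
    sites = int(both.sum())
    if sites == 0:
        return K2PResult(math.nan, math.nan, math.nan, 0, False)
    diff = both & (ca != cb)
    transitions = int((diff & ((ca >> 1) == (cb >> 1))).sum())
    transversions = int(diff.sum()) - transitions
    p = transitions / sites
    q = transversions / sites
    w1 = 1.0 - 2.0 * p - q
    w2 = 1.0 - 2.0 * q
    if w1 <= 0.0 or w2 <= 0.0:
        return K2PResult(math.nan, p, q, sites, False)
    d = -0.5 * math.log(w1 * math.sqrt(w2))
    return K2PResult(d, p, q, sites, True)


@dataclass
class DistanceMatrix:
    """Symmetric K2P distance matrix with an applicability mask.

    ``values[i, j]`` is in substitutions/site; entries where ``applicable`` is
    False (saturated or zero-overlap pairs) hold nan and must be skipped by
    every downstream statistic.  ``comparable_sites[i, j]`` counts the
    pairwise-complete columns used for that pair.
    """

    ids: list[str]
    values: np.ndarray
    applicable: np.ndarray
    comparable_sites: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.ids)
        assert self.values.shape == (n, n)
        assert self.applicable.shape == (n, n)
        assert self.comparable_sites.shape == (n, n)

    def __len__(self) -> int:
        return len(self.ids)

    def index_of(self, id_: str) -> int:
        return self.ids.index(id_)

    @property
    def n_inapplicable_pairs(self) -> int:
        iu = np.triu_indices(len(self.ids), k=1)
        return int((~self.applicable[iu]).sum())

    def submatrix(self, ids: Sequence[str]) -> "DistanceMatrix":
        idx = np.array([self.index_of(i) for i in ids])
        return DistanceMatrix(
            ids=list(ids),
            values=self.values[np.ix_(idx, idx)],
            applicable=self.applicable[np.ix_(idx, idx)],
            comparable_sites=self.comparable_sites[np.ix_(idx, idx)],
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)

    def write_tsv(self, path: str | Path) -> None:
        """Square TSV with ids as header row/column; inapplicable pairs blank."""
        df = self.to_dataframe().copy()
        df = df.where(pd.DataFrame(self.applicable, index=self.ids, columns=self.ids))
        df.to_csv(path, sep="\t", float_format="%.8f", na_rep="")

    def condensed(self) -> np.ndarray:
        """Upper-triangle distances in scipy condensed order (nan where masked)."""
        iu = np.triu_indices(len(self.ids), k=1)
        return self.values[iu]


def pairwise_matrix(ds: GenusDataset) -> DistanceMatrix:
    """All-pairs K2P distances for a dataset (haplotype or full-sequence view)."""
    if len(ds) < 2:
        raise ValueError("pairwise_matrix needs at least 2 sequences")
    codes = np.vstack([encode(r.residues) for r in ds.records])
    n = len(ds)
    values = np.zeros((n, n))
    applicable = np.ones((n, n), dtype=bool)
    sites = np.zeros((n, n), dtype=np.int64)
    for i in range(n):
        sites[i, i] = int((codes[i] != 255).sum())
        for j in range(i + 1, n):
            res = k2p_distance(codes[i], codes[j])
            values[i, j] = values[j, i] = res.distance if res.applicable else np.nan
            applicable[i, j] = applicable[j, i] = res.applicable
            sites[i, j] = sites[j, i] = res.sites
    m = DistanceMatrix(ids=ds.ids, values=values, applicable=applicable, comparable_sites=sites)
    if m.n_inapplicable_pairs:
        logger.warning(
            "%s: %d of %d pairs inapplicable (no overlap or saturated); masked",
            ds.genus, m.n_inapplicable_pairs, n * (n - 1) // 2,
        )
    return m


@dataclass
class SpeciesDistanceSummary:
    """Intra- and interspecific distance summaries for one species.

    ``min_inter`` / ``mean_inter`` are keyed by the *other* species of each
    congeneric pair.  A species represented by a single sequence (or whose
    within-species pairs are all masked) gets max_intra = mean_intra = 0 with
    ``n_intra_pairs = 0``; the flag lets callers treat that 0 with caution.
    """

    species: str
    max_intra: float
    mean_intra: float
    n_intra_pairs: int
    min_inter: dict[str, float] = field(default_factory=dict)
    mean_inter: dict[str, float] = field(default_factory=dict)

    @property
    def overall_min_inter(self) -> float | None:
        if not self.min_inter:
            return None
        return min(self.min_inter.values())

    @property
    def nearest_congener(self) -> str | None:
        if not self.min_inter:
            return None
        return min(self.min_inter, key=lambda s: (self.min_inter[s], s))


def summarize_by_species(
    m: DistanceMatrix, labels: Mapping[str, str]
) -> list[SpeciesDistanceSummary]:
    """Per-species intra/inter distance summaries over applicable pairs.

    In a full-sequence (redundancy-retained) view, duplicate haplotypes enter
    as distinct sequences, so their zero distances pull intraspecific means
    down — that is the intended contrast with the unique-haplotype view.
    """
    unlabeled = [i for i in m.ids if i not in labels]
    if unlabeled:
        raise MetadataError(f"ids without species labels: {unlabeled}")
    species_order: list[str] = []
    members: dict[str, list[int]] = {}
    for idx, id_ in enumerate(m.ids):
        sp = labels[id_]
        if sp not in members:
            members[sp] = []
            species_order.append(sp)
        members[sp].append(idx)

    out: list[SpeciesDistanceSummary] = []
    for sp in species_order:
        rows = np.array(members[sp])
        intra_vals: list[float] = []
        if len(rows) > 1:
            sub_ok = m.applicable[np.ix_(rows, rows)]
            sub_d = m.values[np.ix_(rows, rows)]
            iu = np.triu_indices(len(rows), k=1)
            ok = sub_ok[iu]
            intra_vals = list(sub_d[iu][ok])
        if intra_vals:
            summ = SpeciesDistanceSummary(
                species=sp,
                max_intra=float(np.max(intra_vals)),
                mean_intra=float(np.mean(intra_vals)),
                n_intra_pairs=len(intra_vals),
            )
        else:
            summ = SpeciesDistanceSummary(sp, 0.0, 0.0, 0)
        for other in species_order:
            if other == sp:
                continue
            cols = np.array(members[other])
            blk_ok = m.applicable[np.ix_(rows, cols)]
            blk_d = m.values[np.ix_(rows, cols)]
            vals = blk_d[blk_ok]
            if vals.size:
                summ.min_inter[other] = float(vals.min())
                summ.mean_inter[other] = float(vals.mean())
        out.append(summ)
    return out
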