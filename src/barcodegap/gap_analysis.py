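"""Local (per-species) and global (per-genus) barcoding-gap detection.

A species has a **local barcoding gap** when its minimum interspecific K2P
distance to any congener strictly exceeds its maximum intraspecific distance;
such a species can be identified from a barcode alone.  A genus has a
**global barcoding gap** when the distribution of per-species mean
intraspecific distances does not overlap the distribution of per-species-pair
mean interspecific distances; divergent specimens can then be flagged as
provisional species.  When a global gap exists its magnitude is the ratio of
the genus mean interspecific to mean intraspecific distance, which threshold
rules (the classic 10x rule, or a laxer 5x) compare against a multiplier.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .distances import DistanceMatrix, SpeciesDistanceSummary

logger = logging.getLogger(__name__)

DEFAULT_MULTIPLIERS = (10.0, 5.0)


@dataclass(frozen=True)
class SpeciesGapRecord:
    """Local-gap outcome for one species."""

    species: str
    max_intra: float
    min_inter: float
    gap_present: bool
    nearest_congener: str


def local_gaps(summaries: list[SpeciesDistanceSummary]) -> list[SpeciesGapRecord]:
    """Classify each species by the strict min-inter > max-intra rule.

    Species with no applicable interspecific pair are logged and excluded.
    In a scatter of max-intra (x) vs min-inter (y), gap-present species fall
    strictly above the 1:1 line; shared haplotypes force min_inter = 0 and
    thus gap absence.
    """
    out: list[SpeciesGapRecord] = []
    for s in summaries:
        mi = s.overall_min_inter
        if mi is None:
            logger.warning("%s: no applicable interspecific pair; excluded from local-gap test", s.species)
            continue
        out.append(
            SpeciesGapRecord(
                species=s.species,
                max_intra=s.max_intra,
                min_inter=mi,
                gap_present=mi > s.max_intra,
                nearest_congener=s.nearest_congener or "",
            )
        )
    return out


def local_gaps_dataframe(records: list[SpeciesGapRecord]) -> pd.DataFrame:
    """Scatterplot-ready table (x = max_intra, y = min_inter)."""
    return pd.DataFrame(
        [
            {
                "species": r.species,
                "max_intra": r.max_intra,
                "min_inter": r.min_inter,
                "gap_present": r.gap_present,
                "nearest_congener": r.nearest_congener,
            }
            for r in records
        ]
    )


@dataclass
class GenusGapRecord:
    """Global-gap outcome for one genus.

    ``intra_means`` holds one mean intraspecific distance per species and
    ``inter_means`` one mean interspecific distance per species pair; the gap
    test asks whether the two distributions overlap.  ``threshold_ratio`` is
    mean_inter / mean_intra and is reported only when the gap is present
    (and left None when mean_intra is 0, where the ratio is undefined).
    """

    genus: str
    intra_means: dict[str, float]
    inter_means: dict[tuple[str, str], float]
    mean_intra: float
    mean_inter: float
    gap_present: bool
    threshold_ratio: float | None
    meets_rule: dict[float, bool] = field(default_factory=dict)
    pooling: str = "species_means"


def global_gap(
    summaries: list[SpeciesDistanceSummary],
    genus: str,
    multipliers: tuple[float, ...] = DEFAULT_MULTIPLIERS,
    pooling: str = "species_means",
    matrix: DistanceMatrix | None = None,
    labels: dict[str, str] | None = None,
) -> GenusGapRecord:
    """Test a genus for a global barcoding gap and evaluate threshold rules.

    With the default ``pooling="species_means"`` the intra distribution is the
    per-species mean intraspecific distances and the inter distribution the
    per-species-pair mean interspecific distances; genus means average these,
    unweighted.  ``pooling="raw_pairs"`` instead pools every applicable raw
    pairwise distance (requires ``matrix`` and ``labels``); the overlap test
    always uses the species-level distributions.
    """
    if len(summaries) < 2:
        raise ValueError("global_gap needs at least 2 species")
    # species with no measured within-species pair contribute no intra value
    # (their placeholder 0 is not a measurement), but still enter inter pairs
    intra_means = {s.species: s.mean_intra for s in summaries if s.n_intra_pairs > 0}
    if not intra_means:
        raise ValueError(f"{genus}: no species with an intraspecific pair")
    inter_means: dict[tuple[str, str], float] = {}
    for s in summaries:
        for other, val in s.mean_inter.items():
            key = tuple(sorted((s.species, other)))
            inter_means.setdefault(key, val)  # symmetric blocks give equal means
    if not inter_means:
        raise ValueError(f"{genus}: no applicable interspecific pairs")

    intra_vals = np.array(list(intra_means.values()))
    inter_vals = np.array(list(inter_means.values()))
    gap_present = bool(intra_vals.max() < inter_vals.min())  # strict; ties = overlap

    if pooling == "species_means":
        mean_intra = float(intra_vals.mean())
        mean_inter = float(inter_vals.mean())
    elif pooling == "raw_pairs":
        if matrix is None or labels is None:
            raise ValueError("raw_pairs pooling requires matrix and labels")
        mean_intra, mean_inter = _raw_pair_means(matrix, labels)
    else:
        raise ValueError(f"unknown pooling mode: {pooling}")

    if mean_intra > 0:
        ratio = mean_inter / mean_intra
    else:
        ratio = None
        logger.warning("%s: all species monomorphic (mean intra 0); threshold ratio undefined", genus)
    threshold_ratio = ratio if gap_present else None
    meets = {
        m: (threshold_ratio is not None and threshold_ratio >= m) for m in multipliers
    }
    return GenusGapRecord(
        genus=genus,
        intra_means=intra_means,
        inter_means=inter_means,
        mean_intra=mean_intra,
        mean_inter=mean_inter,
        gap_present=gap_present,
        threshold_ratio=threshold_ratio,
        meets_rule=meets,
        pooling=pooling,
    )


def _raw_pair_means(m: DistanceMatrix, labels: dict[str, str]) -> tuple[float, float]:
    sp = np.array([labels[i] for i in m.ids])
    same = sp[:, None] == sp[None, :]
    iu = np.triu_indices(len(m.ids), k=1)
    ok = m.applicable[iu]
    vals = m.values[iu]
    intra = vals[ok & same[iu]]
    inter = vals[ok & ~same[iu]]
    if intra.size == 0 or inter.size == 0:
        raise ValueError("raw_pairs pooling: empty intra or inter pair set")
    return float(intra.mean()), float(inter.mean())


def global_gap_dataframe(rec: GenusGapRecord) -> pd.DataFrame:
    """One-row summary table; distances rendered as % sequence divergence."""
    return pd.DataFrame(
        [
            {
                "genus": rec.genus,
                "mean_intra_pct": round(rec.mean_intra * 100, 1),
                "mean_inter_pct": round(rec.mean_inter * 100, 1),
                "gap_present": rec.gap_present,
                "threshold_ratio": (
                    f"{rec.threshold_ratio:.1f}x" if rec.threshold_ratio is not None else ""
                ),
            }
        ]
    )


def histogram_dataframe(rec: GenusGapRecord) -> pd.DataFrame:
    """Long-format distribution data for the global-gap histogram."""
    rows = [
        {"genus": rec.genus, "kind": "intra", "unit": sp, "distance": v}
        for sp, v in rec.intra_means.items()
    ] + [
        {"genus": rec.genus, "kind": "inter", "unit": f"{a}|{b}", "distance": v}
        for (a, b), v in rec.inter_means.items()
    ]
    return pd.DataFrame(rows)
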