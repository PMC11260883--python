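"""Pilot procedure for choosing minimum acceptable sample sizes.

Accurate intraspecific distance means need enough haplotypes/sequences, but a
demanding threshold excludes species.  The pilot takes a richly sampled
single-species dataset, treats its full-data mean intraspecific K2P distance
as the "true" value, and asks how small a random subsample can get before the
estimate departs from or varies too much around that benchmark.  The smallest
size meeting both a relative-deviation and a relative-spread tolerance is the
recommended minimum.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .distances import DistanceMatrix, pairwise_matrix
from .seq_io import GenusDataset

logger = logging.getLogger(__name__)


def _mean_applicable(m: DistanceMatrix, idx: np.ndarray | None = None) -> float:
    if idx is None:
        idx = np.arange(len(m.ids))
    sub_ok = m.applicable[np.ix_(idx, idx)]
    sub_d = m.values[np.ix_(idx, idx)]
    iu = np.triu_indices(len(idx), k=1)
    ok = sub_ok[iu]
    if not ok.any():
        raise ValueError("no applicable pairwise distances in subsample")
    return float(sub_d[iu][ok].mean())


def benchmark_mean(ds: GenusDataset) -> float:
    """Mean applicable pairwise K2P distance over all sequences (the 'truth')."""
    if len(ds) < 2:
        raise ValueError("benchmark_mean needs at least 2 sequences")
    return _mean_applicable(pairwise_matrix(ds))


@dataclass(frozen=True)
class PilotRow:
    size: int
    replicate_means: tuple[float, ...]
    mean_of_means: float
    sd_of_means: float
    mean_abs_rel_dev: float  # mean |replicate mean - truth| / truth


@dataclass(frozen=True)
class PilotResult:
    truth: float
    rows: tuple[PilotRow, ...]
    replicates: int
    seed: int

    def to_dataframe(self) -> pd.DataFrame:
        """Long format: one row per (size, replicate)."""
        recs = [
            {"size": row.size, "replicate": k, "mean_distance": m}
            for row in self.rows
            for k, m in enumerate(row.replicate_means)
        ]
        return pd.DataFrame(recs)

    def summary_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "size": r.size,
                    "mean_of_means": r.mean_of_means,
                    "sd_of_means": r.sd_of_means,
                    "mean_abs_rel_dev": r.mean_abs_rel_dev,
                }
                for r in self.rows
            ]
        )


def subsample_curve(
    ds: GenusDataset,
    sizes: list[int],
    replicates: int = 10,
    seed: int = 0,
) -> PilotResult:
    """Replicate subsampling curve of mean pairwise distance vs sample size.

    Each replicate draws ``size`` sequences uniformly without replacement and
    records the mean applicable pairwise distance of the subsample.  The full
    distance matrix is computed once; deterministic given ``seed``.
    """
    sizes = sorted(set(sizes))
    if any(s < 2 for s in sizes):
        raise ValueError("subset sizes must be >= 2")
    if max(sizes) > len(ds):
        raise ValueError(f"max size {max(sizes)} exceeds dataset size {len(ds)}")
    m = pairwise_matrix(ds)
    truth = _mean_applicable(m)
    rng = np.random.default_rng(seed)
    n = len(ds)
    rows: list[PilotRow] = []
    for size in sizes:
        means = []
        for _ in range(replicates):
            # sorted so summation order (and thus the full-size case) is exact
            idx = np.sort(rng.choice(n, size=size, replace=False))
            means.append(_mean_applicable(m, idx))
        arr = np.array(means)
        if np.all(arr == arr[0]):
            sd = 0.0  # identical replicates: avoid roundoff in np.std
        else:
            sd = float(arr.std(ddof=1)) if replicates > 1 else 0.0
        rows.append(
            PilotRow(
                size=size,
                replicate_means=tuple(means),
                mean_of_means=float(arr.mean()),
                sd_of_means=sd,
                mean_abs_rel_dev=(
                    float(np.abs(arr - truth).mean() / truth) if truth > 0 else float("nan")
                ),
            )
        )
    return PilotResult(truth=truth, rows=tuple(rows), replicates=replicates, seed=seed)


def select_minimum(
    res: PilotResult, max_rel_dev: float = 0.10, max_rel_sd: float = 0.10
) -> int:
    """Smallest subset size meeting both convergence tolerances.

    A size qualifies when its mean absolute relative deviation from the truth
    is <= ``max_rel_dev`` and its sd-of-means / truth is <= ``max_rel_sd``.
    If no size qualifies the largest size is returned with a warning.
    """
    if not res.rows:
        raise ValueError("empty pilot result")
    if res.truth == 0:
        raise ValueError(
            "benchmark mean distance is 0; relative criteria undefined "
            "(use an absolute tolerance instead)"
        )
    for row in res.rows:
        if row.mean_abs_rel_dev <= max_rel_dev and row.sd_of_means / res.truth <= max_rel_sd:
            return row.size
    largest = res.rows[-1].size
    logger.warning(
        "no subset size met tolerances (dev<=%.2f, sd<=%.2f); falling back to largest size %d",
        max_rel_dev, max_rel_sd, largest,
    )
    return largest
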