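"""Distance-based species delimitation via a ranked single-linkage sweep.

Candidate partitions are generated by ascending hierarchical (single-linkage)
clustering of the K2P matrix: one partition per distinct merge height, from
all-singletons down to one cluster.  Each partition is scored by two
quantities in the spirit of automatic barcode-gap partitioning:

* ``p_panmixia`` — an add-one permutation probability that randomly
  reassigning sequences to clusters of the same sizes produces a
  within/between mean-distance ratio at least as extreme (small) as observed;
  low values mean the clusters are real structure, not sampling noise.
* ``w`` — the relative barcode gap width: (minimum between-cluster distance
  minus maximum within-cluster distance) divided by the overall mean pairwise
  distance, floored at 0.  Larger is better.

Partitions are ranked on each metric (rank 1 = best: lowest p, largest w) and
the final score is the average of the two ranks; the lowest score wins, ties
resolved in favor of fewer delimited species.  Partitions that place nearly
every sequence in its own cluster are excluded from selection as implausible.

These scores are this package's own explicit formulas, documented above;
partitions produced by external delimitation tools can be imported instead
and fed directly to the concordance stage.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform
from scipy.stats import rankdata

from .distances import DistanceMatrix

logger = logging.getLogger(__name__)

DEFAULT_PLAUSIBILITY_CAP = 0.9


@dataclass(frozen=True)
class Partition:
    """An assignment of every sequence id to a delimited-species cluster.

    Cluster ids are contiguous integers from 1, numbered by the
    lexicographically smallest member id of each cluster.  ``cut_height`` is
    the merge height that produced the partition (None for imported ones).
    """

    assignment: dict[str, int]
    cut_height: float | None = None

    @property
    def n_clusters(self) -> int:
        return len(set(self.assignment.values()))

    def clusters(self) -> dict[int, frozenset[str]]:
        out: dict[int, set[str]] = {}
        for id_, c in self.assignment.items():
            out.setdefault(c, set()).add(id_)
        return {c: frozenset(v) for c, v in out.items()}

    def to_dataframe(self) -> pd.DataFrame:
        rows = sorted(self.assignment.items())
        return pd.DataFrame(rows, columns=["id", "cluster"])

    def write_tsv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False)


def _canonical(assignment: dict[str, int], cut_height: float | None) -> Partition:
    """Relabel clusters contiguously from 1 by smallest member id."""
    by_cluster: dict[int, list[str]] = {}
    for id_, c in assignment.items():
        by_cluster.setdefault(c, []).append(id_)
    order = sorted(by_cluster, key=lambda c: min(by_cluster[c]))
    remap = {c: k + 1 for k, c in enumerate(order)}
    return Partition({id_: remap[c] for id_, c in assignment.items()}, cut_height)


def candidate_partitions(m: DistanceMatrix) -> list[Partition]:
    """All partitions along the single-linkage dendrogram of the matrix.

    Requires a fully applicable matrix: a masked (saturated/zero-overlap)
    pair has no defined distance to cluster on, so callers must drop the
    offending sequences first.  Output runs from the all-singletons partition
    (cut height None) through one partition per distinct merge height.
    """
    n = len(m.ids)
    if n < 2:
        raise ValueError("need at least 2 sequences to partition")
    iu = np.triu_indices(n, k=1)
    if not m.applicable[iu].all():
        bad = [
            (m.ids[i], m.ids[j])
            for i, j in zip(*iu)
            if not m.applicable[i, j]
        ]
        raise ValueError(
            f"matrix has {len(bad)} inapplicable pairs (e.g. {bad[0]}); "
            "drop those sequences before delimitation"
        )
    order = np.argsort(np.array(m.ids))  # lexicographic id order for tie determinism
    ids = [m.ids[k] for k in order]
    sq = m.values[np.ix_(order, order)]
    Z = linkage(squareform(sq, checks=False), method="single")

    partitions: list[Partition] = [
        _canonical({id_: k + 1 for k, id_ in enumerate(ids)}, None)
    ]
    # replay the merges with union-find, snapshotting after each distinct height
    parent = list(range(2 * n - 1))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    heights = Z[:, 2]
    for row in range(n - 1):
        a, b = int(Z[row, 0]), int(Z[row, 1])
        new = n + row
        parent[find(a)] = new
        parent[find(b)] = new
        last_at_height = row == n - 2 or heights[row + 1] > heights[row]
        if last_at_height:
            assignment = {ids[i]: find(i) for i in range(n)}
            partitions.append(_canonical(assignment, float(heights[row])))
    return partitions


@dataclass
class PartitionScore:
    """Gap-width and panmixia metrics for one candidate partition.

    ``rank_w``, ``rank_p`` and ``score`` are filled in by
    :func:`rank_partitions`, since ranks are relative to the candidate set.
    """

    n_clusters: int
    w: float
    p_panmixia: float
    rank_w: float | None = None
    rank_p: float | None = None
    score: float | None = None


def score_partition(
    p: Partition, m: DistanceMatrix, n_perm: int = 999, seed: int = 0
) -> PartitionScore:
    """Compute gap width W and the permutation panmixia probability.

    The panmixia statistic is mean-within / mean-between distance; the
    permutation null shuffles which ids belong to which cluster, keeping
    cluster sizes fixed.  With no within-cluster pair (all clusters
    singletons) the within statistics are taken as 0.
    """
    if not (2 <= p.n_clusters <= len(m.ids)):
        raise ValueError("scoring requires 2 <= n_clusters <= n")
    labels = np.array([p.assignment[id_] for id_ in m.ids])
    n = len(labels)
    iu0, iu1 = np.triu_indices(n, k=1)
    d = m.values[iu0, iu1]
    same = labels[iu0] == labels[iu1]

    overall_mean = float(d.mean())
    within = d[same]
    between = d[~same]
    max_within = float(within.max()) if within.size else 0.0
    min_between = float(between.min()) if between.size else 0.0
    w = 0.0
    if overall_mean > 0:
        w = max(0.0, (min_between - max_within) / overall_mean)

    obs = _within_between_ratio(d.sum(), float(within.sum()), int(same.sum()), d.size)
    rng = np.random.default_rng(seed)
    perms = rng.permuted(np.tile(labels, (n_perm, 1)), axis=1)
    same_p = perms[:, iu0] == perms[:, iu1]  # (n_perm, n_pairs)
    w_sum = same_p @ d
    w_cnt = same_p.sum(axis=1)
    stats = np.array(
        [
            _within_between_ratio(d.sum(), float(ws), int(wc), d.size)
            for ws, wc in zip(w_sum, w_cnt)
        ]
    )
    count = int((stats <= obs + _TIE_TOL).sum())
    p_panmixia = (1 + count) / (1 + n_perm)
    return PartitionScore(n_clusters=p.n_clusters, w=w, p_panmixia=p_panmixia)


_TIE_TOL = 1e-12


def _within_between_ratio(total: float, within_sum: float, within_cnt: int, n_pairs: int) -> float:
    """Mean-within / mean-between from pair sums; 0/0 counts as 0."""
    between_cnt = n_pairs - within_cnt
    mw = within_sum / within_cnt if within_cnt else 0.0
    mb = (total - within_sum) / between_cnt if between_cnt else 0.0
    if mb <= 0.0:
        return 0.0 if mw <= 0.0 else math.inf
    return mw / mb


@dataclass(frozen=True)
class RankedPartitions:
    """Scored candidates sorted best-first, plus the selected partition."""

    ranked: tuple[tuple[Partition, PartitionScore], ...]
    selected: Partition

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "n_clusters": s.n_clusters,
                    "cut_height": p.cut_height,
                    "w": s.w,
                    "p_panmixia": s.p_panmixia,
                    "rank_w": s.rank_w,
                    "rank_p": s.rank_p,
                    "score": s.score,
                }
                for p, s in self.ranked
            ]
        )


def rank_partitions(
    candidates: list[tuple[Partition, PartitionScore]],
    plausibility_cap: float = DEFAULT_PLAUSIBILITY_CAP,
) -> RankedPartitions:
    """Average-rank scoring and selection with a fewer-species tie-break.

    W is ranked descending (larger gap better), p ascending (lower better);
    the score is the mean of the two ranks (average ranks on ties).  The
    selected partition is the lowest-scoring one, ties going to fewer
    clusters; partitions with more than ``plausibility_cap * n`` clusters
    (nearly one sequence per delimited species) are never selected.
    """
    if not candidates:
        raise ValueError("no scored partitions")
    ws = np.array([s.w for _, s in candidates])
    ps = np.array([s.p_panmixia for _, s in candidates])
    rank_w = rankdata(-ws, method="average")
    rank_p = rankdata(ps, method="average")
    for k, (_, s) in enumerate(candidates):
        s.rank_w = float(rank_w[k])
        s.rank_p = float(rank_p[k])
        s.score = (s.rank_w + s.rank_p) / 2.0

    ranked = sorted(candidates, key=lambda t: (t[1].score, t[1].n_clusters))
    n = len(ranked[0][0].assignment)
    eligible = [
        (p, s) for p, s in ranked if s.n_clusters <= plausibility_cap * n
    ]
    if not eligible:
        raise ValueError(
            f"every partition exceeds the plausibility cap ({plausibility_cap} * {n} ids)"
        )
    return RankedPartitions(ranked=tuple(ranked), selected=eligible[0][0])


def import_partition(tsv_path: str | Path, expected_ids: list[str] | None = None) -> Partition:
    """Read an externally produced partition (two-column TSV: id, cluster).

    Lets output from external delimitation tools (e.g. tree-based methods)
    feed the concordance stage.  If ``expected_ids`` is given, the file must
    cover exactly that id set.
    """
    df = pd.read_csv(tsv_path, sep="\t", dtype=str)
    if list(df.columns[:2]) != ["id", "cluster"]:
        raise ValueError(f"expected columns id, cluster; got {list(df.columns)}")
    if df["id"].duplicated().any():
        dupes = sorted(df.loc[df["id"].duplicated(), "id"])
        raise ValueError(f"duplicate ids in partition file: {dupes}")
    assignment_raw = dict(zip(df["id"], df["cluster"]))
    if expected_ids is not None:
        got, want = set(assignment_raw), set(expected_ids)
        if got != want:
            missing, extra = sorted(want - got), sorted(got - want)
            raise ValueError(f"partition id mismatch: missing {missing}, extra {extra}")
    # map arbitrary cluster labels to contiguous ints
    labels = {c: k for k, c in enumerate(dict.fromkeys(assignment_raw.values()))}
    return _canonical({i: labels[c] for i, c in assignment_raw.items()}, None)
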