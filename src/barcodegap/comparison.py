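"""Permutation comparison of distance summaries between dataset views.

The unique-haplotype and all-sequences views of a genus can differ both in
species composition and in how redundant haplotypes weight the distance
means.  To ask whether a genus' per-species mean intraspecific distances (or
per-species-pair mean interspecific distances) differ between the two views,
we use a two-group randomization ANOVA: the observed one-way F statistic is
compared against its distribution under random relabeling of the pooled
values.

Because the total sum of squares is invariant under relabeling, F is a
monotone function of the between-group sum of squares, which is what the
permutation loop actually compares.  The reported p-value uses the add-one
convention p = (1 + #{permuted >= observed}) / (1 + iterations), so p is
never exactly 0.  When the number of distinct label assignments is small the
null is enumerated exhaustively instead of sampled.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np

logger = logging.getLogger(__name__)

#: enumerate the null exactly when C(n_a + n_b, n_a) is at most this
EXHAUSTIVE_LIMIT = 50_000
_TIE_TOL = 1e-12


@dataclass(frozen=True)
class PermutationResult:
    statistic: float  # observed one-way F (inf when within-group variance is 0)
    p_value: float
    iterations: int  # permutations drawn, or assignments enumerated
    seed: int | None
    group_sizes: tuple[int, int]
    exhaustive: bool = False


def _ssb(values: np.ndarray, n_a: int) -> float:
    """Between-group sum of squares for the first-n_a / rest split."""
    gm = values.mean()
    a, b = values[:n_a], values[n_a:]
    return n_a * (a.mean() - gm) ** 2 + len(b) * (b.mean() - gm) ** 2


def permutation_test(
    a: list[float],
    b: list[float],
    iterations: int = 10_000,
    seed: int | None = None,
) -> PermutationResult:
    """Two-group randomization test on an F-like variance-ratio statistic.

    ``a`` and ``b`` are the per-species (or per-species-pair) mean distances
    from the two dataset views, treated as independent groups.  Deterministic
    given ``seed``.  Zero total variance yields p = 1 by convention.
    """
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 values")
    x = np.concatenate([np.asarray(a, dtype=float), np.asarray(b, dtype=float)])
    n_a, n_b = len(a), len(b)
    n = n_a + n_b

    sst = float(((x - x.mean()) ** 2).sum())
    if sst <= _TIE_TOL:
        logger.warning("zero total variance; p = 1 by convention")
        return PermutationResult(0.0, 1.0, 0, seed, (n_a, n_b))

    obs_ssb = _ssb(x, n_a)
    ssw = sst - obs_ssb
    statistic = math.inf if ssw <= _TIE_TOL else (obs_ssb / 1.0) / (ssw / (n - 2))

    n_assignments = math.comb(n, n_a)
    if n_assignments <= EXHAUSTIVE_LIMIT:
        count = 0
        for combo in combinations(range(n), n_a):
            mask = np.zeros(n, dtype=bool)
            mask[list(combo)] = True
            perm = np.concatenate([x[mask], x[~mask]])
            if _ssb(perm, n_a) >= obs_ssb - _TIE_TOL:
                count += 1
        p = (1 + count) / (1 + n_assignments)
        return PermutationResult(statistic, p, n_assignments, seed, (n_a, n_b), exhaustive=True)

    rng = np.random.default_rng(seed)
    perms = rng.permuted(np.tile(x, (iterations, 1)), axis=1)
    gm = x.mean()
    ssb = n_a * (perms[:, :n_a].mean(axis=1) - gm) ** 2 + n_b * (
        perms[:, n_a:].mean(axis=1) - gm
    ) ** 2
    count = int((ssb >= obs_ssb - _TIE_TOL).sum())
    p = (1 + count) / (1 + iterations)
    return PermutationResult(statistic, p, iterations, seed, (n_a, n_b))
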