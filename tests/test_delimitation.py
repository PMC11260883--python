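"""Single-linkage partition sweep, gap-width/panmixia scoring, and ranking."""

import numpy as np
import pytest

from barcodegap.delimitation import (
    Partition,
    PartitionScore,
    candidate_partitions,
    import_partition,
    rank_partitions,
    score_partition,
)
from barcodegap.distances import DistanceMatrix, pairwise_matrix
from barcodegap.haplotypes import collapse_haplotypes

from conftest import make_dataset


def matrix_from_values(ids, values):
    values = np.asarray(values, dtype=float)
    return DistanceMatrix(
        ids=list(ids),
        values=values,
        applicable=np.ones_like(values, dtype=bool),
        comparable_sites=np.full_like(values, 100, dtype=np.int64),
    )


def two_group_matrix():
    """6 points: {a,b,c} within 0.01, {d,e,f} within 0.01, 0.10 apart."""
    ids = list("abcdef")
    v = np.zeros((6, 6))
    for i in range(6):
        for j in range(6):
            if i == j:
                continue
            same = (i < 3) == (j < 3)
            v[i, j] = 0.01 if same else 0.10
    return matrix_from_values(ids, v)


class TestCandidatePartitions:
    def test_all_zero_distances_two_partitions(self):
        m = matrix_from_values("abc", np.zeros((3, 3)))
        parts = candidate_partitions(m)
        assert len(parts) == 2  # singletons + single merge height at 0
        assert parts[0].n_clusters == 3
        assert parts[1].n_clusters == 1

    def test_two_groups_appear_at_expected_heights(self):
        parts = candidate_partitions(two_group_matrix())
        by_k = {p.n_clusters: p for p in parts}
        assert set(by_k) == {6, 2, 1}
        two = by_k[2]
        clusters = {frozenset(c) for c in two.clusters().values()}
        assert clusters == {frozenset("abc"), frozenset("def")}
        assert two.cut_height == pytest.approx(0.01)
        assert by_k[1].cut_height == pytest.approx(0.10)

    def test_count_is_distinct_heights_plus_one(self, sim_genus):
        _, ds, _ = sim_genus
        table = collapse_haplotypes(ds)
        reps = [h.representative for sp in table.species for h in table.entries[sp]]
        nh = make_dataset(ds.genus, [(r.id, r.species, r.residues) for r in reps])
        m = pairwise_matrix(nh)
        parts = candidate_partitions(m)
        heights = {p.cut_height for p in parts if p.cut_height is not None}
        assert len(parts) == len(heights) + 1

    def test_masked_pair_rejected(self):
        v = np.zeros((3, 3))
        m = matrix_from_values("abc", v)
        m.applicable[0, 1] = m.applicable[1, 0] = False
        with pytest.raises(ValueError, match="inapplicable"):
            candidate_partitions(m)

    def test_cluster_ids_contiguous_from_one(self):
        for p in candidate_partitions(two_group_matrix()):
            assert sorted(set(p.assignment.values())) == list(
                range(1, p.n_clusters + 1)
            )


class TestScorePartition:
    def test_gap_width_hand_arithmetic(self):
        # within <= 0.01, between >= 0.10; overall mean of the 15 pairs:
        # 6 within pairs at 0.01 + 9 between at 0.10 -> 0.064
        m = two_group_matrix()
        part = {i: (1 if i in "abc" else 2) for i in "abcdef"}
        score = score_partition(Partition(part), m, n_perm=99, seed=1)
        overall = (6 * 0.01 + 9 * 0.10) / 15
        assert score.w == pytest.approx((0.10 - 0.01) / overall)

    def test_w_negative_floored_at_zero(self):
        m = two_group_matrix()
        # deliberately bad partition mixing the groups
        part = {"a": 1, "b": 2, "c": 1, "d": 2, "e": 1, "f": 2}
        score = score_partition(Partition(part), m, n_perm=49, seed=1)
        assert score.w == 0.0

    def test_w_scale_invariant(self):
        m = two_group_matrix()
        m2 = matrix_from_values(m.ids, m.values * 3.7)
        part = Partition({i: (1 if i in "abc" else 2) for i in "abcdef"})
        s1 = score_partition(part, m, n_perm=9, seed=0)
        s2 = score_partition(part, m2, n_perm=9, seed=0)
        assert s1.w == pytest.approx(s2.w)

    def test_separated_clusters_reach_minimum_p(self):
        # large enough that a random permutation essentially never recreates
        # the observed grouping (tie probability 2/C(14,7)), so the observed
        # ratio is strictly the most extreme
        n = 14
        ids = [f"s{k}" for k in range(n)]
        v = np.full((n, n), 0.10)
        for i in range(n):
            for j in range(n):
                if (i < 7) == (j < 7):
                    v[i, j] = 0.01
        np.fill_diagonal(v, 0.0)
        m = matrix_from_values(ids, v)
        part = Partition({f"s{k}": (1 if k < 7 else 2) for k in range(n)})
        score = score_partition(part, m, n_perm=199, seed=3)
        assert score.p_panmixia == pytest.approx(1 / 200)

    def test_structureless_data_rarely_significant(self):
        # under the null, p is roughly uniform, so p < 0.05 in ~5% of seeds
        rng = np.random.default_rng(17)
        n = 12
        ok = 0
        n_seeds = 50
        for seed in range(n_seeds):
            d = rng.uniform(0.01, 0.03, size=(n, n))
            d = (d + d.T) / 2
            np.fill_diagonal(d, 0)
            m = matrix_from_values([f"s{k}" for k in range(n)], d)
            labels = {f"s{k}": 1 + (k % 3) for k in range(n)}
            score = score_partition(Partition(labels), m, n_perm=199, seed=seed)
            if score.p_panmixia >= 0.05:
                ok += 1
        assert ok >= 0.9 * n_seeds

    def test_deterministic_given_seed(self):
        m = two_group_matrix()
        part = Partition({i: (1 if i in "abc" else 2) for i in "abcdef"})
        s1 = score_partition(part, m, n_perm=99, seed=5)
        s2 = score_partition(part, m, n_perm=99, seed=5)
        assert s1 == s2


def fake_scored(pairs):
    """Build (Partition, PartitionScore) list from (n_clusters, w, p) on 10 ids."""
    out = []
    ids = [f"s{k}" for k in range(10)]
    for n_clusters, w, p in pairs:
        assign = {i: min(k + 1, n_clusters) for k, i in enumerate(ids)}
        out.append(
            (Partition(assign), PartitionScore(n_clusters=n_clusters, w=w, p_panmixia=p))
        )
    return out


class TestRankPartitions:
    def test_best_score_selected(self):
        scored = fake_scored([(2, 1.5, 0.01), (4, 0.5, 0.30)])
        ranked = rank_partitions(scored)
        assert ranked.selected.n_clusters == 2
        assert ranked.ranked[0][1].score == 1.0

    def test_tie_broken_by_fewer_clusters(self):
        # one partition wins on w, the other on p -> tied average rank
        scored = fake_scored([(7, 1.5, 0.30), (4, 0.5, 0.01)])
        ranked = rank_partitions(scored)
        assert ranked.ranked[0][1].score == ranked.ranked[1][1].score == 1.5
        assert ranked.selected.n_clusters == 4

    def test_near_singleton_partition_never_selected(self):
        scored = fake_scored([(10, 5.0, 0.001), (2, 0.5, 0.40)])
        ranked = rank_partitions(scored, plausibility_cap=0.9)
        assert ranked.ranked[0][1].n_clusters == 10  # best score...
        assert ranked.selected.n_clusters == 2  # ...but not selectable

    def test_all_excluded_is_error(self):
        scored = fake_scored([(10, 5.0, 0.001)])
        with pytest.raises(ValueError, match="plausibility cap"):
            rank_partitions(scored, plausibility_cap=0.9)


class TestImportPartition:
    def test_round_trip_identity(self, tmp_path):
        part = Partition({"a": 1, "b": 1, "c": 2})
        path = tmp_path / "part.tsv"
        part.write_tsv(path)
        back = import_partition(path, expected_ids=["a", "b", "c"])
        assert back.assignment == part.assignment

    def test_cluster_labels_normalized(self, tmp_path):
        path = tmp_path / "part.tsv"
        path.write_text("id\tcluster\nx\tspA\ny\tspA\nz\tspB\n")
        part = import_partition(path)
        assert part.assignment == {"x": 1, "y": 1, "z": 2}

    def test_missing_id_rejected(self, tmp_path):
        path = tmp_path / "part.tsv"
        path.write_text("id\tcluster\na\t1\n")
        with pytest.raises(ValueError, match="mismatch"):
            import_partition(path, expected_ids=["a", "b"])

    def test_duplicate_id_rejected(self, tmp_path):
        path = tmp_path / "part.tsv"
        path.write_text("id\tcluster\na\t1\na\t2\n")
        with pytest.raises(ValueError, match="duplicate"):
            import_partition(path)


class TestTruthRecovery:
    def test_recovers_true_species_on_separated_genus(self, sim_genus):
        # 5x separation between inter and intra depths: the selected
        # partition should equal the true species assignment
        _, ds, _ = sim_genus
        table = collapse_haplotypes(ds)
        reps = [h.representative for sp in table.species for h in table.entries[sp]]
        nh = make_dataset(ds.genus, [(r.id, r.species, r.residues) for r in reps])
        m = pairwise_matrix(nh)
        scored = [
            (p, score_partition(p, m, n_perm=99, seed=1))
            for p in candidate_partitions(m)
            if p.n_clusters >= 2
        ]
        sel = rank_partitions(scored).selected
        truth_clusters = {
            frozenset(r.id for r in nh.records if r.species == sp) for sp in nh.species
        }
        assert {frozenset(c) for c in sel.clusters().values()} == truth_clusters
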