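"""K2P distance computation, masking, and per-species summaries."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from barcodegap.distances import (
    k2p_distance,
    pairwise_matrix,
    summarize_by_species,
)
from barcodegap.seq_io import AlignmentError, MetadataError

from conftest import make_dataset


def k2p_reference(a: str, b: str):
    """Independent brute-force K2P: per-site loop, no shared code."""
    purines = {"A", "G"}
    pyrimidines = {"C", "T"}
    sites = ts = tv = 0
    for x, y in zip(a.upper(), b.upper()):
        if x not in "ACGT" or y not in "ACGT":
            continue
        sites += 1
        if x == y:
            continue
        if (x in purines and y in purines) or (x in pyrimidines and y in pyrimidines):
            ts += 1
        else:
            tv += 1
    if sites == 0:
        return None
    p, q = ts / sites, tv / sites
    arg1, arg2 = 1 - 2 * p - q, 1 - 2 * q
    if arg1 <= 0 or arg2 <= 0:
        return None
    return -0.5 * math.log(arg1 * math.sqrt(arg2))


SEQ = st.text(alphabet="ACGTN-", min_size=1, max_size=80)


class TestK2P:
    def test_identical_sequences_give_zero(self):
        r = k2p_distance("ACGT" * 25, "ACGT" * 25)
        assert r.distance == 0.0 and r.p == 0.0 and r.q == 0.0 and r.sites == 100

    def test_closed_form_ten_transitions(self):
        # 100 sites, 10 transitions (A->G), 0 transversions
        a = "A" * 100
        b = "G" * 10 + "A" * 90
        r = k2p_distance(a, b)
        assert r.p == 0.1 and r.q == 0.0
        assert r.distance == pytest.approx(-0.5 * math.log(0.8), abs=1e-12)
        assert r.distance == pytest.approx(0.11157, abs=5e-6)

    def test_saturated_pair_inapplicable(self):
        # P=0.25, Q=0.5 -> 1-2Q = 0, log undefined
        a = "A" * 4
        b = "G" + "C" + "T" + "A"
        r = k2p_distance(a, b)
        assert r.p == 0.25 and r.q == 0.5
        assert not r.applicable and math.isnan(r.distance)

    def test_no_overlap_inapplicable(self):
        r = k2p_distance("ANNN", "N--N")
        assert r.sites == 0 and not r.applicable

    def test_length_mismatch_raises(self):
        with pytest.raises(AlignmentError):
            k2p_distance("ACGT", "ACG")

    def test_ambiguity_codes_excluded_from_sites(self):
        r = k2p_distance("ARGT", "AYGT")
        assert r.sites == 3  # R/Y columns dropped pairwise

    @given(a=SEQ, b=SEQ)
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_matches_reference_and_is_symmetric(self, a, b):
        n = min(len(a), len(b))
        a, b = a[:n], b[:n]
        ours = k2p_distance(a, b)
        theirs = k2p_distance(b, a)
        assert ours.sites == theirs.sites
        if ours.sites > 0:
            assert ours.p == theirs.p and ours.q == theirs.q
        ref = k2p_reference(a, b)
        if ref is None:
            assert not ours.applicable
        else:
            assert ours.applicable
            assert ours.distance == theirs.distance  # exact symmetry
            assert ours.distance == pytest.approx(ref, abs=1e-12)

    @given(a=SEQ, b=SEQ)
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_distance_at_least_p_distance(self, a, b):
        n = min(len(a), len(b))
        r = k2p_distance(a[:n], b[:n])
        if r.applicable:
            assert r.distance >= r.p + r.q - 1e-12


class TestPairwiseMatrix:
    def test_identical_sequences_zero_matrix(self):
        ds = make_dataset("G", [(f"s{k}", "x", "ACGT" * 10) for k in range(3)])
        m = pairwise_matrix(ds)
        assert np.all(m.values == 0.0) and m.applicable.all()

    def test_matches_per_pair_recomputation(self, sim_genus):
        _, ds, _ = sim_genus
        sub = ds.subset(ds.ids[:10])
        m = pairwise_matrix(sub)
        for i, j in itertools.combinations(range(10), 2):
            ref = k2p_reference(sub.records[i].residues, sub.records[j].residues)
            assert m.values[i, j] == pytest.approx(ref, abs=1e-12)
            assert m.values[i, j] == m.values[j, i]
        assert np.all(np.diag(m.values) == 0.0)

    def test_masked_pairs_counted(self):
        ds = make_dataset(
            "G",
            [("s1", "x", "AAAANNNN"), ("s2", "x", "NNNNAAAA"), ("s3", "x", "AAAAAAAA")],
        )
        m = pairwise_matrix(ds)
        assert m.n_inapplicable_pairs == 1
        assert not m.applicable[0, 1]
        assert m.applicable[0, 2] and m.applicable[1, 2]


class TestSummaries:
    def test_single_pair_species(self):
        ds = make_dataset(
            "G",
            [
                ("x1", "x", "A" * 98 + "GG"),
                ("x2", "x", "A" * 100),
                ("y1", "y", "C" * 50 + "A" * 50),
            ],
        )
        m = pairwise_matrix(ds)
        (sx, sy) = summarize_by_species(m, ds.species_labels)
        expected = k2p_reference("A" * 98 + "GG", "A" * 100)
        assert sx.max_intra == sx.mean_intra == pytest.approx(expected)
        assert sx.n_intra_pairs == 1
        assert sy.n_intra_pairs == 0 and sy.max_intra == 0.0

    def test_shared_haplotype_gives_zero_min_inter(self):
        ds = make_dataset(
            "G",
            [
                ("x1", "x", "ACGTACGT"),
                ("x2", "x", "ACGTACGA"),
                ("y1", "y", "ACGTACGT"),
                ("y2", "y", "TTTTACGT"),
            ],
        )
        m = pairwise_matrix(ds)
        summaries = {s.species: s for s in summarize_by_species(m, ds.species_labels)}
        assert summaries["x"].min_inter["y"] == 0.0
        assert summaries["x"].nearest_congener == "y"

    def test_matches_brute_force_enumeration(self, sim_genus):
        # oracle: recompute every statistic by direct enumeration over pairs
        _, ds, _ = sim_genus
        ids = [r.id for r in ds.records if r.id.endswith("_r01")][:12]
        sub = ds.subset(ids)
        m = pairwise_matrix(sub)
        labels = sub.species_labels
        summaries = {s.species: s for s in summarize_by_species(m, labels)}
        by_sp = {}
        for r in sub.records:
            by_sp.setdefault(r.species, []).append(r)
        for sp, recs in by_sp.items():
            intra = [
                k2p_reference(a.residues, b.residues)
                for a, b in itertools.combinations(recs, 2)
            ]
            intra = [d for d in intra if d is not None]
            if intra:
                assert summaries[sp].max_intra == pytest.approx(max(intra), abs=1e-12)
                assert summaries[sp].mean_intra == pytest.approx(
                    sum(intra) / len(intra), abs=1e-12
                )
            for other, orecs in by_sp.items():
                if other == sp:
                    continue
                inter = [
                    k2p_reference(a.residues, b.residues)
                    for a in recs
                    for b in orecs
                ]
                inter = [d for d in inter if d is not None]
                assert summaries[sp].min_inter[other] == pytest.approx(
                    min(inter), abs=1e-12
                )
                assert summaries[sp].mean_inter[other] == pytest.approx(
                    sum(inter) / len(inter), abs=1e-12
                )

    def test_unlabeled_id_rejected(self, two_species_ds):
        m = pairwise_matrix(two_species_ds)
        with pytest.raises(MetadataError):
            summarize_by_species(m, {"a1": "x"})

    def test_collapsing_duplicates_preserves_distances(self, sim_genus):
        # distances between distinct haplotypes are identical whether or not
        # redundant copies are present
        from barcodegap.haplotypes import collapse_haplotypes

        _, ds, _ = sim_genus
        table = collapse_haplotypes(ds)
        reps = [h.representative for sp in table.species for h in table.entries[sp]]
        full = pairwise_matrix(ds)
        nh = pairwise_matrix(make_dataset(ds.genus, [(r.id, r.species, r.residues) for r in reps]))
        for i, a in enumerate(nh.ids):
            for j in range(i + 1, len(nh.ids)):
                b = nh.ids[j]
                fi, fj = full.index_of(a), full.index_of(b)
                assert nh.values[i, j] == full.values[fi, fj]
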