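"""Local Matching Score, Ward clustering and entropy — oracle-checked.

The naive double-loop LMS and a from-scratch Lance-Williams Ward
implementation live here as independent oracles for the indexed/scipy-backed
implementations in the package.
"""

import math
import random

import numpy as np
import pytest
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from kinout.clap import (
    ClusterReport,
    DistanceMatrix,
    LMSParams,
    cluster_entropy,
    cut_dendrogram,
    distance_matrix,
    lms_distance,
    lms_pair,
    lms_raw,
    outlier_cluster_report,
    ward_tree,
)
from kinout.io import SequenceRecord

AA20 = "ACDEFGHIKLMNPQRSTVWY"

# BLOSUM62 diagonal, transcribed independently of the package
B62_DIAG = {
    "A": 4, "R": 5, "N": 6, "D": 6, "C": 9, "Q": 5, "E": 5, "G": 6, "H": 8,
    "I": 4, "L": 4, "K": 5, "M": 5, "F": 6, "P": 7, "S": 4, "T": 5, "W": 11,
    "Y": 7, "V": 4,
}


def naive_lms_raw(seq, w=5):
    return sum(
        sum(B62_DIAG[c] for c in seq[i : i + w]) for i in range(len(seq) - w + 1)
    )


def naive_lms_pair(a, b, w=5):
    """Window-by-window double loop: a window of one sequence scores iff its
    word equals some window of the other."""
    total = 0
    for x, y in ((a, b), (b, a)):
        for i in range(len(x) - w + 1):
            word = x[i : i + w]
            if any(word == y[j : j + w] for j in range(len(y) - w + 1)):
                total += sum(B62_DIAG[c] for c in word)
    return total


def naive_lms_distance(a, b, w=5):
    return 1.0 - naive_lms_pair(a, b, w) / (naive_lms_raw(a, w) + naive_lms_raw(b, w))


def random_protein(rng, lo=10, hi=60):
    return "".join(rng.choice(AA20) for _ in range(rng.randrange(lo, hi + 1)))


class TestLmsRaw:
    def test_single_window_of_alanines(self):
        assert lms_raw("AAAAA") == 5 * 4

    def test_two_windows(self):
        assert lms_raw("AAAAAA") == 2 * 5 * 4

    def test_against_blosum_enumeration(self):
        # expected value computed by summing published BLOSUM62 diagonals
        # over the 6 windows of MKTAYIAKQR: 26+25+24+24+25+23
        assert naive_lms_raw("MKTAYIAKQR") == 147
        assert lms_raw("MKTAYIAKQR") == 147

    def test_short_sequence_is_error(self):
        with pytest.raises(ValueError):
            lms_raw("MKT")


class TestLmsPair:
    def test_self_pair_is_twice_raw(self):
        for seq in ("MKTAYIAKQR", "AAAAA", "WWWWWCCCCC"):
            assert lms_pair(seq, seq) == 2 * lms_raw(seq)

    def test_disjoint_alphabets_share_nothing(self):
        assert lms_pair("AAAAAAA", "WWWWWWW") == 0

    def test_single_shared_word_counted_from_both_sides(self):
        # only MKTAY (score 26) is shared; counted once per direction
        a, b = "MKTAYIAKQR", "MKTAYWWWWW"
        assert naive_lms_pair(a, b) == 52
        assert lms_pair(a, b) == 52


class TestLmsDistance:
    def test_self_distance_zero(self):
        assert lms_distance("MKTAYIAKQR", "MKTAYIAKQR") == 0.0

    def test_no_shared_word_distance_one(self):
        assert lms_distance("AAAAAAA", "WWWWWWW") == 1.0

    def test_partial_overlap_strictly_between(self):
        d = lms_distance("MKTAYIAKQR", "MKTAYWWWWW")
        assert 0.0 < d < 1.0
        assert d == pytest.approx(naive_lms_distance("MKTAYIAKQR", "MKTAYWWWWW"))

    def test_axioms_on_random_pairs(self):
        rng = random.Random(1234)
        for _ in range(50):
            a, b = random_protein(rng), random_protein(rng)
            d_ab, d_ba = lms_distance(a, b), lms_distance(b, a)
            assert d_ab == d_ba
            assert 0.0 <= d_ab <= 1.0
            assert lms_distance(a, a) == 0.0

    def test_pair_score_gains_appended_shared_word(self):
        """Appending to b a word already present in a raises the matched pair
        score by at least that word's window score."""
        rng = random.Random(99)
        for _ in range(25):
            a = random_protein(rng, 20, 40)
            b = random_protein(rng, 20, 40)
            word = a[:5]
            if word in b:
                continue
            gain = lms_pair(a, b + word) - lms_pair(a, b)
            assert gain >= sum(B62_DIAG[c] for c in word)


class TestDistanceMatrix:
    def test_identical_sequences_off_diagonal_zero(self):
        seqs = [SequenceRecord("a", "MKTAYIAKQR"), SequenceRecord("b", "MKTAYIAKQR")]
        D = distance_matrix(seqs)
        assert D.d[0, 1] == 0.0

    def test_mutually_alien_sequences(self):
        seqs = [
            SequenceRecord("a", "AAAAAAA"),
            SequenceRecord("b", "WWWWWWW"),
            SequenceRecord("c", "CCCCCCC"),
        ]
        D = distance_matrix(seqs)
        off = D.d[~np.eye(3, dtype=bool)]
        assert np.all(off == 1.0)

    def test_duplicate_ids_rejected(self):
        seqs = [SequenceRecord("a", "MKTAYIAKQR"), SequenceRecord("a", "MKTAYWWWWW")]
        with pytest.raises(ValueError, match="duplicate"):
            distance_matrix(seqs)

    def test_indexed_equals_naive_double_loop(self):
        """Oracle equivalence on 50 random sequence pairs of length <= 60."""
        rng = random.Random(2024)
        seqs = [SequenceRecord(f"s{i}", random_protein(rng)) for i in range(20)]
        D = distance_matrix(seqs)
        checked = 0
        for i in range(20):
            for j in range(i + 1, 20):
                if checked >= 50:
                    break
                expected = naive_lms_distance(seqs[i].seq, seqs[j].seq)
                assert D.d[i, j] == pytest.approx(expected, abs=1e-12), (i, j)
                checked += 1
        assert checked == 50


def brute_force_ward(d):
    """From-scratch Ward agglomeration: recompute every cluster-pair cost each
    step via Lance-Williams on squared dissimilarities; smallest-pair
    tie-break.  Returns a scipy-style linkage matrix."""
    n = d.shape[0]
    active = {i: 1 for i in range(n)}  # cluster id -> size
    cost = {}
    for i in range(n):
        for j in range(i + 1, n):
            cost[(i, j)] = d[i, j] ** 2
    Z = []
    next_id = n
    while len(active) > 1:
        (i, j), c = min(cost.items(), key=lambda kv: (kv[1], kv[0]))
        si, sj = active[i], active[j]
        Z.append([i, j, math.sqrt(c), si + sj])
        new_cost = {}
        for (a, b), cab in cost.items():
            if {a, b} & {i, j}:
                continue
            new_cost[(a, b)] = cab
        for k in active:
            if k in (i, j):
                continue
            sk = active[k]
            cik = cost[tuple(sorted((i, k)))]
            cjk = cost[tuple(sorted((j, k)))]
            merged = ((si + sk) * cik + (sj + sk) * cjk - sk * cost[(i, j)]) / (
                si + sj + sk
            )
            new_cost[tuple(sorted((k, next_id)))] = merged
        del active[i], active[j]
        active[next_id] = si + sj
        cost = new_cost
        next_id += 1
    return np.array(Z)


class TestWardTree:
    def test_two_points_single_merge(self):
        D = DistanceMatrix(ids=["a", "b"], d=np.array([[0.0, 0.6], [0.6, 0.0]]))
        tree = ward_tree(D)
        assert tree.linkage.shape == (1, 4)
        assert tree.heights[0] == pytest.approx(0.6)

    def test_nearest_pair_merges_first(self):
        d = np.array([[0.0, 0.05, 0.9], [0.05, 0.0, 0.95], [0.9, 0.95, 0.0]])
        tree = ward_tree(DistanceMatrix(ids=list("abc"), d=d))
        assert set(tree.linkage[0, :2].astype(int)) == {0, 1}

    def test_matches_brute_force_oracle_on_random_matrices(self):
        """Merge structure and heights equal a from-scratch Ward
        implementation on random 8-point matrices (compared through the
        cophenetic matrix, which encodes both)."""
        rng = np.random.default_rng(5)
        for _ in range(10):
            x = rng.random((8, 3))
            d = np.sqrt(((x[:, None, :] - x[None, :, :]) ** 2).sum(-1))
            d = d / (d.max() + 1e-9)
            tree = ward_tree(DistanceMatrix(ids=[f"s{i}" for i in range(8)], d=d))
            Z_oracle = brute_force_ward(d)
            coph_impl = hierarchy.cophenet(tree.linkage)
            coph_oracle = hierarchy.cophenet(Z_oracle)
            assert np.allclose(coph_impl, coph_oracle, atol=1e-9)

    def test_merge_heights_non_decreasing(self):
        rng = np.random.default_rng(11)
        x = rng.random((15, 4))
        d = np.sqrt(((x[:, None, :] - x[None, :, :]) ** 2).sum(-1))
        d = d / d.max()
        tree = ward_tree(DistanceMatrix(ids=[f"s{i}" for i in range(15)], d=d))
        assert np.all(np.diff(tree.heights) >= -1e-12)

    def test_single_point_is_error(self):
        with pytest.raises(ValueError):
            ward_tree(DistanceMatrix(ids=["a"], d=np.zeros((1, 1))))


class TestCutDendrogram:
    def _tree(self):
        rng = np.random.default_rng(3)
        x = np.concatenate([rng.normal(0, 0.02, (5, 2)), rng.normal(1, 0.02, (5, 2))])
        d = np.sqrt(((x[:, None, :] - x[None, :, :]) ** 2).sum(-1))
        d = np.clip(d / d.max(), 0, 1)
        np.fill_diagonal(d, 0)
        return ward_tree(DistanceMatrix(ids=[f"s{i}" for i in range(10)], d=d))

    def test_fraction_one_single_cluster(self):
        tree = self._tree()
        clusters = cut_dendrogram(tree, fraction=1.0)
        assert len(clusters) == 1 and len(clusters[0]) == 10

    def test_tiny_fraction_all_singletons(self):
        tree = self._tree()
        clusters = cut_dendrogram(tree, fraction=1e-9)
        assert len(clusters) == 10

    def test_two_blobs_split_at_quarter_height(self):
        tree = self._tree()
        clusters = cut_dendrogram(tree, fraction=0.25)
        assert sorted(sorted(c) for c in clusters) == [
            [f"s{i}" for i in range(5)], [f"s{i}" for i in range(5, 10)]
        ]

    def test_absolute_height_mode(self):
        tree = self._tree()
        clusters = cut_dendrogram(tree, absolute_height=float(tree.heights.max()) + 1)
        assert len(clusters) == 1

    def test_synthetic_subfamilies_group_together(self):
        """A 3-subfamily kinome cut at 0.25 yields >= 3 clusters grouped by
        subfamily."""
        from kinout import synthetic

        registry, library = synthetic.make_toy_registry(3, seed=7)
        config = synthetic.KinomeConfig(n_sequences=30, n_subfamilies=3, seed=7)
        kinome = synthetic.generate_kinome(registry, library, config)
        D = distance_matrix(kinome.records)
        clusters = cut_dendrogram(ward_tree(D), fraction=0.25)
        assert len(clusters) >= 3
        subfamily = {t.seq_id: t.subfamily for t in kinome.truth}
        for members in clusters:
            assert len({subfamily[m] for m in members}) == 1


class TestClusterEntropy:
    def test_pure_cluster_zero(self):
        assert cluster_entropy(["PKA"] * 10, k_total=91) == 0.0

    def test_uniform_over_all_subfamilies_is_one(self):
        members = [f"SF{i}" for i in range(7)]
        assert cluster_entropy(members, k_total=7) == pytest.approx(1.0)

    def test_eight_two_split_with_k91(self):
        expected = -(0.8 * math.log(0.8) + 0.2 * math.log(0.2)) / math.log(91)
        got = cluster_entropy(["A"] * 8 + ["B"] * 2, k_total=91)
        assert got == pytest.approx(expected)

    def test_k_below_two_is_error(self):
        with pytest.raises(ValueError):
            cluster_entropy(["A"], k_total=1)

    def test_zero_iff_pure(self):
        rng = random.Random(17)
        for _ in range(50):
            k = rng.randrange(2, 8)
            members = [f"SF{rng.randrange(k)}" for _ in range(rng.randrange(1, 12))]
            e = cluster_entropy(members, k_total=10)
            assert (e == 0.0) == (len(set(members)) == 1)
            assert 0.0 <= e <= 1.0


class _Call:
    def __init__(self, seq_id, subfamily, label):
        self.seq_id, self.assigned_subfamily, self.label = seq_id, subfamily, label


class TestOutlierClusterReport:
    def test_pure_canonical_cluster(self):
        calls = [_Call(f"s{i}", "PKA", "canonical") for i in range(5)]
        report = outlier_cluster_report([[c.seq_id for c in calls]], calls, k_total=10)
        assert report.entropy == [0.0]
        assert report.outlier_fraction == [0.0]
        assert report.ignorable() == [True]

    def test_planted_hybrid_raises_entropy(self):
        calls = [_Call(f"s{i}", "MAPK", "canonical") for i in range(9)]
        calls.append(_Call("hyb", "PDGFR", "hybrid_single_domain"))
        report = outlier_cluster_report([[c.seq_id for c in calls]], calls, k_total=10)
        assert report.entropy[0] > 0
        assert report.outlier_fraction[0] == pytest.approx(0.1)

    def test_partition_mismatch_is_error(self):
        calls = [_Call("a", "PKA", "canonical")]
        with pytest.raises(ValueError, match="one-to-one"):
            outlier_cluster_report([["a", "b"]], calls)

    def test_members_partition_dataset(self):
        calls = [_Call(f"s{i}", "PKA", "canonical") for i in range(6)]
        clusters = [["s0", "s1"], ["s2", "s3", "s4"], ["s5"]]
        report = outlier_cluster_report(clusters, calls, k_total=5)
        assert sorted(m for c in report.clusters for m in c) == [f"s{i}" for i in range(6)]


def test_newick_export_is_valid(tmp_path):
    import dendropy

    rng = np.random.default_rng(2)
    x = rng.random((6, 2))
    d = np.sqrt(((x[:, None, :] - x[None, :, :]) ** 2).sum(-1))
    d = np.clip(d / d.max(), 0, 1)
    np.fill_diagonal(d, 0)
    ids = [f"kin{i}" for i in range(6)]
    tree = ward_tree(DistanceMatrix(ids=ids, d=d))
    newick = tree.to_newick()
    parsed = dendropy.Tree.get(data=newick, schema="newick")
    assert sorted(leaf.taxon.label for leaf in parsed.leaf_node_iter()) == sorted(ids)
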