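import itertools
from functools import lru_cache

import numpy as np
import pytest
from scipy import stats as scipy_stats
from skbio import DistanceMatrix as SkbioDM
from skbio.tree import nj as skbio_nj

from palmkit.conservation import (
    DistanceMatrix,
    align_pair,
    identity_distance_matrix,
    is_clade,
    mann_whitney_u,
    neighbor_joining,
    ortholog_identity_stats,
    pair_identity,
    percent_identity,
    tree_to_newick,
)
from palmkit.io import ProteinRecord
from palmkit.simulate import simulate_additive_matrix, simulate_ortholog_pair

from Bio.Align import substitution_matrices

BLOSUM62 = substitution_matrices.load("BLOSUM62")
GAP_OPEN, GAP_EXTEND = 11.0, 1.0


def dp_oracle_global(a: str, b: str) -> float:
    """Independent affine-gap global alignment score by naive recursion.

    States: 0 = last column was a match/mismatch, 1 = gap in b (a consumed),
    2 = gap in a (b consumed).  Opening a gap costs open+extend, extending
    costs extend, matching the scheme under test.
    """
    NEG = float("-inf")

    @lru_cache(maxsize=None)
    def M(i, j):
        if i == 0 and j == 0:
            return 0.0
        if i == 0 or j == 0:
            return NEG
        return max(M(i - 1, j - 1), X(i - 1, j - 1), Y(i - 1, j - 1)) + BLOSUM62[
            a[i - 1]
        ][b[j - 1]]

    @lru_cache(maxsize=None)
    def X(i, j):  # gap in b: a[i-1] aligned to '-'
        if i == 0:
            return NEG
        open_from = max(M(i - 1, j), Y(i - 1, j))
        return max(
            open_from - GAP_OPEN - GAP_EXTEND
            if open_from > NEG
            else NEG,
            X(i - 1, j) - GAP_EXTEND if X(i - 1, j) > NEG else NEG,
        )

    @lru_cache(maxsize=None)
    def Y(i, j):  # gap in a
        if j == 0:
            return NEG
        open_from = max(M(i, j - 1), X(i, j - 1))
        return max(
            open_from - GAP_OPEN - GAP_EXTEND
            if open_from > NEG
            else NEG,
            Y(i, j - 1) - GAP_EXTEND if Y(i, j - 1) > NEG else NEG,
        )

    return max(M(len(a), len(b)), X(len(a), len(b)), Y(len(a), len(b)))


class TestAlignPair:
    def test_identity_alignment(self):
        aln = align_pair("RNYR", "RNYR")
        assert aln.matches == 4 and aln.columns == 4
        assert percent_identity(aln) == 100.0

    def test_single_substitution(self):
        aln = align_pair("RNYR", "RNFR")
        assert aln.matches == 3 and aln.columns == 4
        assert percent_identity(aln) == 75.0

    def test_degapped_aligned_strings_equal_inputs(self):
        a, b = "RNYRACDEFGHK", "RNYRAEFGHK"
        aln = align_pair(a, b)
        assert aln.aligned_a.replace("-", "") == a
        assert aln.aligned_b.replace("-", "") == b

    def test_score_matches_recursive_dp_oracle(self):
        rng = np.random.default_rng(17)
        alphabet = list("ACDEFGHIKLMNPQRSTVWY")
        for _ in range(15):
            a = "".join(rng.choice(alphabet, int(rng.integers(3, 13))))
            b = "".join(rng.choice(alphabet, int(rng.integers(3, 13))))
            assert align_pair(a, b).score == pytest.approx(dp_oracle_global(a, b))

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            align_pair("", "RNYR")


class TestPercentIdentity:
    def test_shorter_sequence_convention(self):
        aln = align_pair("RNYRACDEF", "RNYR", mode="local")
        assert percent_identity(aln, "shorter", "RNYRACDEF", "RNYR") == 100.0

    def test_identity_on_controlled_ortholog_pairs_is_exact(self):
        for ident in (100.0, 93.0, 60.0):
            a, b, true_ident = simulate_ortholog_pair(ident, 300, seed=int(ident))
            assert pair_identity(a, b) == pytest.approx(true_ident)

    def test_identity_zero_boundary(self):
        a, b, true_ident = simulate_ortholog_pair(0.0, 50, seed=1)
        assert true_ident == 0.0
        # alignment may gap rather than pair 50 mismatched columns;
        # the substitution-only identity is checked column-wise instead
        assert sum(x == y for x, y in zip(a.sequence, b.sequence)) == 0


class TestOrthologStats:
    def test_trivial_summaries(self):
        recs = lambda s: ProteinRecord(id=f"r{hash(s) % 99}", sequence=s)
        pairs = [
            (ProteinRecord(id="a1", sequence="RNYR"), ProteinRecord(id="b1", sequence="RNYR")),
            (ProteinRecord(id="a2", sequence="ACDE"), ProteinRecord(id="b2", sequence="ACDE")),
        ]
        stats = ortholog_identity_stats(pairs)
        assert stats["median"] == 100.0
        assert stats["min"] == stats["max"] == 100.0

    def test_odd_count_median_hand_check(self):
        pairs = [
            simulate_ortholog_pair(ident, 100, seed=i)[:2]
            for i, ident in enumerate((60, 93, 99))
        ]
        stats = ortholog_identity_stats(pairs)
        assert stats["median"] == pytest.approx(93.0)
        assert stats["min"] == pytest.approx(60.0)
        assert stats["max"] == pytest.approx(99.0)

    def test_even_count_median_is_midpoint(self):
        pairs = [
            simulate_ortholog_pair(ident, 100, seed=i)[:2]
            for i, ident in enumerate((80, 90))
        ]
        assert ortholog_identity_stats(pairs)["median"] == pytest.approx(85.0)


class TestMannWhitney:
    def test_separated_groups_exact_p(self):
        res = mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert res["U"] == 0.0
        assert res["p"] == pytest.approx(0.1)
        assert res["method"] == "exact"

    def test_identical_multisets_give_p_one(self):
        res = mann_whitney_u([1.0, 1.0, 1.0], [1.0, 1.0])
        assert res["p"] == 1.0

    def test_exact_matches_scipy_enumeration(self):
        rng = np.random.default_rng(23)
        for n_a in range(1, 6):
            for n_b in range(1, 6):
                if n_a + n_b > 10:
                    continue
                values = rng.permutation(np.arange(1.0, n_a + n_b + 1))
                a, b = values[:n_a].tolist(), values[n_a:].tolist()
                ours = mann_whitney_u(a, b)
                ref = scipy_stats.mannwhitneyu(
                    a, b, alternative="two-sided", method="exact"
                )
                assert ours["method"] == "exact"
                assert ours["p"] == pytest.approx(float(ref.pvalue), abs=1e-12)

    def test_large_or_tied_samples_use_asymptotic(self):
        a = list(range(10))
        b = list(range(5, 15))
        res = mann_whitney_u(a, b)
        assert res["method"] == "asymptotic"
        ref = scipy_stats.mannwhitneyu(a, b, alternative="two-sided")
        assert res["p"] == pytest.approx(float(ref.pvalue))


class TestDistanceMatrix:
    def test_identical_sequences_zero_distance(self):
        recs = [ProteinRecord(id=f"r{i}", sequence="RNYRACDEF") for i in range(3)]
        dm = identity_distance_matrix(recs)
        assert np.allclose(dm.values, 0.0)

    def test_entries_match_independent_pairwise_recomputation(self):
        rng = np.random.default_rng(9)
        alphabet = list("ACDEFGHIKLMNPQRSTVWY")
        recs = [
            ProteinRecord(id=f"r{i}", sequence="".join(rng.choice(alphabet, 40)))
            for i in range(4)
        ]
        dm = identity_distance_matrix(recs)
        for i, j in itertools.combinations(range(4), 2):
            expected = 100.0 - pair_identity(recs[i], recs[j])
            assert dm.values[i, j] == pytest.approx(expected)
            assert dm.values[j, i] == pytest.approx(expected)

    def test_validation_rejects_asymmetry(self):
        with pytest.raises(ValueError):
            DistanceMatrix(labels=("a", "b"), values=np.array([[0, 1], [2, 0.0]]))


class TestNeighborJoining:
    def test_three_taxon_hand_solution(self):
        dm = DistanceMatrix(
            labels=("A", "B", "C"),
            values=np.array([[0, 2, 4], [2, 0, 4], [4, 4, 0]], dtype=float),
        )
        tree = neighbor_joining(dm)
        lengths = {t.name: t.length for t in tree.tips()}
        assert lengths == pytest.approx({"A": 1.0, "B": 1.0, "C": 3.0})

    @pytest.mark.parametrize("seed", range(8))
    def test_additive_matrix_exact_recovery(self, seed):
        n = 4 + seed % 5
        true_tree, dm = simulate_additive_matrix(n, seed=seed)
        tree = neighbor_joining(dm)
        dists = tree.tip_tip_distances()
        for a, b in itertools.combinations(dm.labels, 2):
            assert abs(dists[a, b] - dm[a, b]) < 1e-9
        assert _bipartitions(tree) == _bipartitions(true_tree)

    def test_topology_agrees_with_skbio_reference(self):
        _, dm = simulate_additive_matrix(6, seed=42)
        ours = neighbor_joining(dm)
        ref = skbio_nj(SkbioDM(dm.values, ids=list(dm.labels)))
        assert _bipartitions(ours) == _bipartitions(ref)

    def test_internal_nodes_are_degree_three(self):
        _, dm = simulate_additive_matrix(7, seed=1)
        tree = neighbor_joining(dm)
        for node in tree.non_tips(include_self=True):
            degree = len(node.children) + (0 if node.parent is None else 1)
            assert degree == 3


def _bipartitions(tree):
    """Non-trivial splits of the unrooted topology as frozensets."""
    leaves = frozenset(t.name for t in tree.tips())
    splits = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if 1 < len(side) < len(leaves) - 1:
            splits.add(min(side, leaves - side, key=sorted))
    return splits


class TestIsClade:
    @pytest.fixture()
    def balanced_tree(self):
        dm = DistanceMatrix(
            labels=("A", "B", "C", "D"),
            values=np.array(
                [
                    [0, 2, 8, 8],
                    [2, 0, 8, 8],
                    [8, 8, 0, 2],
                    [8, 8, 2, 0],
                ],
                dtype=float,
            ),
        )
        return neighbor_joining(dm)

    def test_singleton_and_full_set_are_clades(self, balanced_tree):
        assert is_clade(balanced_tree, {"A"})
        assert is_clade(balanced_tree, {"A", "B", "C", "D"})

    def test_enumerated_bipartitions(self, balanced_tree):
        assert is_clade(balanced_tree, {"A", "B"})
        assert is_clade(balanced_tree, {"C", "D"})
        assert not is_clade(balanced_tree, {"A", "C"})
        assert is_clade(balanced_tree, {"B", "C", "D"})  # complement of {A}

    def test_unknown_taxon_raises(self, balanced_tree):
        with pytest.raises(ValueError, match="unknown"):
            is_clade(balanced_tree, {"A", "Z"})


class TestNewick:
    def test_fixed_decimal_serialization_is_byte_stable(self):
        _, dm = simulate_additive_matrix(5, seed=2)
        t1 = tree_to_newick(neighbor_joining(dm))
        t2 = tree_to_newick(neighbor_joining(dm))
        assert t1 == t2
        assert t1.endswith(";")
        assert ":" in t1
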