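"""Alignment identity, K2P distances, neighbor-joining, bootstrap."""

import math

import numpy as np
import pytest
from Bio.Align import substitution_matrices
from skbio import DistanceMatrix, TreeNode
from skbio.tree import nj as skbio_nj

from plasmidkit.compare import (
    ComparisonError,
    bootstrap_support,
    global_align,
    k2p_distance,
    k2p_matrix,
    nj_tree,
    ortholog_pairs,
    tree_bipartitions,
)
from plasmidkit.simulate import generate_k2p_alignment

from .conftest import random_seq
from . import oracles

AA = "ACDEFGHIKLMNPQRSTVWY"


def random_tree(rng: np.random.Generator, n: int) -> tuple[TreeNode, list[str]]:
    """Random unrooted binary topology with uniform branch lengths."""
    ids = [f"t{i}" for i in range(n)]
    nodes = [TreeNode(name=i, length=round(float(rng.uniform(0.05, 1.0)), 4))
             for i in ids]
    while len(nodes) > 3:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        parent = TreeNode(length=round(float(rng.uniform(0.05, 1.0)), 4))
        b = nodes.pop(j)
        a = nodes.pop(i)
        parent.extend([a, b])
        nodes.append(parent)
    root = TreeNode()
    root.extend(nodes)
    return root, ids


def path_distance_matrix(tree: TreeNode, ids: list[str]) -> np.ndarray:
    n = len(ids)
    D = np.zeros((n, n))
    tips = {t.name: t for t in tree.tips()}
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = tips[ids[i]].distance(tips[ids[j]])
    return D


class TestGlobalAlign:
    def test_identical_sequences(self):
        aln = global_align("ACGTACGT", "ACGTACGT")
        assert aln.identity_pct == 100.0

    def test_three_quarters(self):
        assert global_align("ACGT", "ACGA").identity_pct == 75.0

    def test_identity_symmetry(self):
        a, b = random_seq(1, 120), random_seq(2, 130)
        assert global_align(a, b).identity_pct == pytest.approx(
            global_align(b, a).identity_pct)

    def test_identity_100_iff_identical(self):
        a = random_seq(3, 80)
        b = a[:40] + ("A" if a[40] != "A" else "C") + a[41:]
        assert global_align(a, b).identity_pct < 100.0

    def test_protein_score_equals_dp_oracle(self):
        """BLOSUM62 affine-gap global score equals an independent Gotoh DP."""
        rng = np.random.default_rng(8)
        a = "".join(rng.choice(list(AA), size=200))
        b = "".join(rng.choice(list(AA), size=190))
        blosum = substitution_matrices.load("BLOSUM62")
        want = oracles.nw_score_oracle(
            a, b, lambda x, y: float(blosum[x, y]), -10.0, -1.0)
        got = global_align(a, b, molecule="aa")
        assert got.score == pytest.approx(want)

    def test_nt_score_equals_dp_oracle(self):
        a, b = random_seq(4, 150), random_seq(5, 160)
        want = oracles.nw_score_oracle(
            a, b, lambda x, y: 1.0 if x == y else -1.0, -2.0, -2.0)
        assert global_align(a, b).score == pytest.approx(want)

    def test_denominator_choice(self):
        aln_all = global_align("ACGTACGT", "ACGT")
        aln_ungapped = global_align("ACGTACGT", "ACGT",
                                    denominator="ungapped_columns")
        assert aln_all.identity_pct < aln_ungapped.identity_pct


class TestK2P:
    def test_identical(self):
        r = k2p_distance("ACGTACGT", "ACGTACGT")
        assert (r.P, r.Q, r.d) == (0.0, 0.0, 0.0)

    def test_closed_form(self):
        """P = 0.1, Q = 0.05 gives d = 0.170182."""
        a = "A" * 100
        b = "G" * 10 + "C" * 5 + "A" * 85
        r = k2p_distance(a, b)
        assert (r.P, r.Q) == (0.1, 0.05)
        assert r.d == pytest.approx(0.170182, abs=1e-6)

    def test_jukes_cantor_limit(self):
        """With Q = 2P the K2P distance collapses to Jukes-Cantor."""
        for P in (0.02, 0.05, 0.08):
            sites = 1000
            ts = int(P * sites)
            tv = 2 * ts
            a = "A" * sites
            b = "G" * ts + "C" * tv + "A" * (sites - ts - tv)
            r = k2p_distance(a, b)
            jc = -0.75 * math.log(1 - (4.0 / 3.0) * (r.P + r.Q))
            assert r.d == pytest.approx(jc, abs=1e-9)

    def test_saturation_raises(self):
        with pytest.raises(ComparisonError, match="saturated"):
            k2p_distance("A" * 10, "G" * 10)

    def test_symmetry_and_monotonicity(self):
        a = "A" * 200

        def d(ts, tv):
            b = "G" * ts + "C" * tv + "A" * (200 - ts - tv)
            return k2p_distance(a, b).d

        assert d(10, 6) == k2p_distance(
            "G" * 10 + "C" * 6 + "A" * 184, a).d
        assert d(12, 6) > d(10, 6)
        assert d(10, 8) > d(10, 6)

    def test_gap_columns_excluded(self):
        r = k2p_distance("AC-GT", "ACNGT")
        assert r.d == 0.0


class TestNJ:
    def test_three_taxa_closed_form(self):
        D = np.array([[0.0, 0.3, 0.5],
                      [0.3, 0.0, 0.6],
                      [0.5, 0.6, 0.0]])
        tree = nj_tree(D, ["a", "b", "c"])
        lengths = {t.name: t.length for t in tree.tips()}
        assert lengths["a"] == pytest.approx(0.5 * (0.3 + 0.5 - 0.6))
        assert lengths["b"] == pytest.approx(0.5 * (0.3 + 0.6 - 0.5))
        assert lengths["c"] == pytest.approx(0.5 * (0.5 + 0.6 - 0.3))

    def test_additive_five_taxon_exact(self):
        rng = np.random.default_rng(0)
        tree, ids = random_tree(rng, 5)
        D = path_distance_matrix(tree, ids)
        rec = nj_tree(D, ids)
        assert np.allclose(path_distance_matrix(rec, ids), D, atol=1e-9)
        assert tree_bipartitions(rec) == tree_bipartitions(tree)

    @pytest.mark.parametrize("seed", range(20))
    def test_recovers_random_additive_matrices(self, seed):
        """NJ is exact on additive (four-point-condition) matrices."""
        rng = np.random.default_rng(100 + seed)
        n = int(rng.integers(5, 9))
        tree, ids = random_tree(rng, n)
        D = path_distance_matrix(tree, ids)
        rec = nj_tree(D, ids)
        assert tree_bipartitions(rec) == tree_bipartitions(tree)
        assert np.allclose(path_distance_matrix(rec, ids), D, atol=1e-9)

    def test_taxon_permutation_isomorphic(self):
        rng = np.random.default_rng(7)
        tree, ids = random_tree(rng, 6)
        D = path_distance_matrix(tree, ids)
        perm = list(rng.permutation(len(ids)))
        Dp = D[np.ix_(perm, perm)]
        idsp = [ids[k] for k in perm]
        assert tree_bipartitions(nj_tree(D, ids)) == \
            tree_bipartitions(nj_tree(Dp, idsp))

    def test_matches_skbio_reference(self):
        """Independent cross-check against scikit-bio's NJ."""
        rng = np.random.default_rng(11)
        tree, ids = random_tree(rng, 7)
        D = path_distance_matrix(tree, ids)
        ours = nj_tree(D, ids)
        ref = skbio_nj(DistanceMatrix(D, ids))
        assert tree_bipartitions(ours) == tree_bipartitions(ref)

    def test_invalid_matrix_rejected(self):
        with pytest.raises(ComparisonError):
            nj_tree(np.array([[0.0, 1.0], [2.0, 0.0]]), ["a", "b"])
        bad = np.array([[0.0, 1.0, 1.0], [1.0, 0.0, 1.0], [1.0, 1.1, 0.0]])
        with pytest.raises(ComparisonError):
            nj_tree(bad, ["a", "b", "c"])


class TestBootstrap:
    def test_invariant_columns_give_full_support(self):
        """Duplicated diagnostic blocks leave no column variation to
        disturb the split, so its support is 100."""
        seqs = {"A": "A" * 400, "B": "A" * 400,
                "C": "G" * 40 + "A" * 360, "D": "G" * 40 + "A" * 360}
        tree = bootstrap_support(seqs, n_reps=50, seed=0)
        supports = [int(n.name) for n in tree.non_tips(include_self=False)
                    if n.name is not None]
        assert supports and all(s == 100 for s in supports)

    def test_single_replicate_support_binary(self):
        rng = np.random.default_rng(1)
        tree = TreeNode.read(["((A:0.1,B:0.1):0.2,(C:0.1,D:0.1):0.2);"])
        seqs = generate_k2p_alignment(tree, 500, seed=3)
        boot = bootstrap_support(seqs, n_reps=1, seed=4)
        supports = [int(n.name) for n in boot.non_tips(include_self=False)
                    if n.name is not None]
        assert set(supports) <= {0, 100}

    def test_long_internal_branch_strongly_supported(self):
        """A long internal branch in a 5-taxon K2P simulation gets
        bootstrap support >= 90 at 100 replicates."""
        gen = TreeNode.read(
            ["((A:0.05,B:0.05):0.4,(C:0.05,D:0.05):0.4,E:0.3);"])
        seqs = generate_k2p_alignment(gen, 2000, ts_tv_ratio=2.0, seed=13)
        boot = bootstrap_support(seqs, n_reps=100, seed=13)
        ab = frozenset({"A", "B"})
        for node in boot.non_tips(include_self=False):
            side = frozenset(t.name for t in node.tips())
            if side == ab or side == frozenset("CDE"):
                assert int(node.name) >= 90
                break
        else:
            raise AssertionError("AB|CDE split not in tree")


class TestOrthologs:
    def test_identical_plasmids_pair_every_orf(self):
        rng = np.random.default_rng(2)
        prot = {f"o{i}": "".join(rng.choice(list(AA), size=80))
                for i in range(4)}
        pairs = ortholog_pairs(prot, dict(prot))
        assert len(pairs) == 4
        assert all(a == b and ident == 100.0 for a, b, ident in pairs)

    def test_disjoint_random_orfs_empty(self):
        rng = np.random.default_rng(3)
        pa = {f"a{i}": "".join(rng.choice(list(AA), size=90))
              for i in range(3)}
        pb = {f"b{i}": "".join(rng.choice(list(AA), size=90))
              for i in range(3)}
        assert ortholog_pairs(pa, pb) == []

    def test_planted_homolog_pair_found(self):
        rng = np.random.default_rng(15)
        rep = "".join(rng.choice(list(AA), size=100))
        mutated = list(rep)
        for pos in rng.choice(100, size=10, replace=False):
            mutated[pos] = AA[(AA.index(mutated[pos]) + 1) % 20]
        pa = {"repA": rep,
              "x1": "".join(rng.choice(list(AA), size=90))}
        pb = {"repB": "".join(mutated),
              "y1": "".join(rng.choice(list(AA), size=90))}
        pairs = ortholog_pairs(pa, pb)
        assert [(a, b) for a, b, _ in pairs] == [("repA", "repB")]
        assert pairs[0][2] == pytest.approx(90.0, abs=1.0)
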