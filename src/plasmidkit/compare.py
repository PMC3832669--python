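"""Pairwise identity, Kimura two-parameter distances, neighbor-joining.

The comparative stage mirrors classical small-replicon phylogenetics:
global (Needleman-Wunsch) alignments for percent identity, the Kimura
two-parameter correction separating transitions from transversions, and
Saitou-Nei neighbor-joining with nonparametric bootstrap supports.

Percent identity is computed over *all* alignment columns (gap columns
included) by default; this denominator choice alone moves identities by
several points, so it is configurable.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices
from skbio import TreeNode

log = logging.getLogger("plasmidkit")

TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}
_NT = set("ACGT")


class ComparisonError(ValueError):
    pass


@dataclass
class PairwiseAlignment:
    aligned_a: str
    aligned_b: str
    matches: int
    columns: int
    score: float

    @property
    def identity_pct(self) -> float:
        return 100.0 * self.matches / self.columns


@dataclass
class K2PDistance:
    P: float  # transition proportion
    Q: float  # transversion proportion
    d: float  # substitutions per site


def _aligner(molecule: str) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    if molecule == "nt":
        aligner.match_score = 1
        aligner.mismatch_score = -1
        aligner.open_gap_score = -2
        aligner.extend_gap_score = -2
    elif molecule == "aa":
        aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
        aligner.open_gap_score = -10
        aligner.extend_gap_score = -1
    else:
        raise ComparisonError(f"unknown molecule type {molecule!r}")
    return aligner


def global_align(a: str, b: str, molecule: str = "nt",
                 denominator: str = "all_columns") -> PairwiseAlignment:
    """Needleman-Wunsch global alignment with percent identity.

    ``denominator`` is ``all_columns`` (default) or ``ungapped_columns``.
    """
    a, b = a.upper(), b.upper()
    if not a or not b:
        raise ComparisonError("empty sequence")
    aln = _aligner(molecule).align(a, b)[0]
    ga, gb = str(aln[0]), str(aln[1])
    matches = sum(1 for x, y in zip(ga, gb) if x == y and x != "-")
    if denominator == "all_columns":
        columns = len(ga)
    elif denominator == "ungapped_columns":
        columns = sum(1 for x, y in zip(ga, gb) if x != "-" and y != "-")
    else:
        raise ComparisonError(f"unknown denominator {denominator!r}")
    return PairwiseAlignment(ga, gb, matches, columns, float(aln.score))


def k2p_distance(a: str, b: str) -> K2PDistance:
    """Kimura two-parameter distance between two aligned sequences.

    Columns with a gap or ambiguous base in either sequence are excluded
    pairwise.  d = -1/2 ln(1 - 2P - Q) - 1/4 ln(1 - 2Q).
    """
    a, b = a.upper(), b.upper()
    if len(a) != len(b):
        raise ComparisonError("aligned sequences differ in length")
    sites = ts = tv = 0
    for x, y in zip(a, b):
        if x not in _NT or y not in _NT:
            continue
        sites += 1
        if x != y:
            if (x, y) in TRANSITIONS:
                ts += 1
            else:
                tv += 1
    if sites == 0:
        raise ComparisonError("no comparable sites")
    P, Q = ts / sites, tv / sites
    w1 = 1.0 - 2.0 * P - Q
    w2 = 1.0 - 2.0 * Q
    if w1 <= 0 or w2 <= 0:
        raise ComparisonError("distance saturated (log domain violation)")
    d = -0.5 * math.log(w1) - 0.25 * math.log(w2) + 0.0  # avoid -0.0
    return K2PDistance(P=P, Q=Q, d=d)


def k2p_matrix(seqs: dict[str, str]) -> tuple[np.ndarray, list[str]]:
    """Symmetric K2P distance matrix from a dict of aligned sequences."""
    ids = list(seqs)
    n = len(ids)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = k2p_distance(seqs[ids[i]], seqs[ids[j]]).d
    return D, ids


def nj_tree(D: np.ndarray, ids: list[str]) -> TreeNode:
    """Saitou-Nei neighbor-joining on a symmetric distance matrix.

    Deterministic: ties in the Q criterion are broken by the smallest
    (i, j) index pair.  Negative branch lengths are clamped to zero and
    logged.  Returns an unrooted tree (trifurcating root) as a scikit-bio
    TreeNode.
    """
    D = np.asarray(D, dtype=float)
    n = D.shape[0]
    if D.shape != (n, n) or n != len(ids):
        raise ComparisonError("matrix/ids shape mismatch")
    if n < 3:
        raise ComparisonError("need at least 3 taxa")
    if not np.allclose(D, D.T) or not np.allclose(np.diag(D), 0):
        raise ComparisonError("matrix must be symmetric with zero diagonal")

    def clamp(x: float) -> float:
        if x < 0:
            log.debug("clamping negative branch length %.4g to 0", x)
            return 0.0
        return x

    nodes: list[TreeNode] = [TreeNode(name=i) for i in ids]
    Dw = D.copy()
    while len(nodes) > 3:
        m = len(nodes)
        totals = Dw.sum(axis=1)
        best = None
        for i in range(m):
            for j in range(i + 1, m):
                q = (m - 2) * Dw[i, j] - totals[i] - totals[j]
                if best is None or q < best[0] - 1e-12:
                    best = (q, i, j)
        _, i, j = best
        di = 0.5 * Dw[i, j] + (totals[i] - totals[j]) / (2.0 * (m - 2))
        dj = Dw[i, j] - di
        parent = TreeNode()
        nodes[i].length = clamp(di)
        nodes[j].length = clamp(dj)
        parent.extend([nodes[i], nodes[j]])
        new_row = 0.5 * (Dw[i, :] + Dw[j, :] - Dw[i, j])
        keep = [k for k in range(m) if k not in (i, j)]
        Dn = np.empty((m - 1, m - 1))
        Dn[:-1, :-1] = Dw[np.ix_(keep, keep)]
        Dn[-1, :-1] = Dn[:-1, -1] = new_row[keep]
        Dn[-1, -1] = 0.0
        nodes = [nodes[k] for k in keep] + [parent]
        Dw = Dn

    root = TreeNode()
    if len(nodes) == 3:
        d01, d02, d12 = Dw[0, 1], Dw[0, 2], Dw[1, 2]
        lens = [0.5 * (d01 + d02 - d12),
                0.5 * (d01 + d12 - d02),
                0.5 * (d02 + d12 - d01)]
        for node, ln in zip(nodes, lens):
            node.length = clamp(ln)
        root.extend(nodes)
    else:  # n == 2 never reaches here; kept for safety
        root.extend(nodes)
    return root


def tree_bipartitions(tree: TreeNode) -> set[frozenset[str]]:
    """Non-trivial bipartitions of an unrooted tree, as smaller leaf sets."""
    leaves = frozenset(t.name for t in tree.tips())
    parts = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if 1 < len(side) < len(leaves) - 1:
            other = leaves - side
            parts.add(min(side, other, key=lambda s: (len(s), sorted(s))))
    return parts


def bootstrap_support(seqs: dict[str, str], n_reps: int = 1000,
                      seed: int = 0) -> TreeNode:
    """NJ tree from a multiple alignment, with bootstrap supports.

    Alignment columns are resampled with replacement per replicate; K2P
    distances and NJ are recomputed, and each internal node of the
    original tree is labeled with the percentage of replicates containing
    its bipartition.  All-gap columns are dropped up front.
    """
    ids = list(seqs)
    if len(ids) < 4:
        raise ComparisonError("bootstrap needs >= 4 taxa")
    if n_reps < 1:
        raise ComparisonError("n_reps must be >= 1")
    length = len(next(iter(seqs.values())))
    if any(len(s) != length for s in seqs.values()):
        raise ComparisonError("alignment rows differ in length")
    cols = np.array([[s[k] for s in seqs.values()] for k in range(length)])
    usable = [k for k in range(length)
              if any(c in _NT for c in cols[k])]
    if len(usable) < length:
        log.warning("dropped %d all-gap/ambiguous columns", length - len(usable))
    mat = {name: "".join(seqs[name][k] for k in usable) for name in ids}

    D, _ = k2p_matrix(mat)
    tree = nj_tree(D, ids)

    rng = np.random.default_rng(seed)
    counts: dict[frozenset[str], int] = {p: 0 for p in tree_bipartitions(tree)}
    m = len(usable)
    rows = {name: np.frombuffer(mat[name].encode(), dtype="S1") for name in ids}
    for _ in range(n_reps):
        idx = rng.integers(0, m, size=m)
        rep = {name: rows[name][idx].tobytes().decode() for name in ids}
        try:
            Dr, _ = k2p_matrix(rep)
            rep_parts = tree_bipartitions(nj_tree(Dr, ids))
        except ComparisonError:
            continue
        for p in counts:
            if p in rep_parts:
                counts[p] += 1

    for node in tree.non_tips(include_self=False):
        leaves = frozenset(t.name for t in tree.tips())
        side = frozenset(t.name for t in node.tips())
        key = min(side, leaves - side, key=lambda s: (len(s), sorted(s)))
        if key in counts:
            node.name = str(round(100.0 * counts[key] / n_reps))
    return tree


def ortholog_pairs(orfs_a: dict[str, str], orfs_b: dict[str, str],
                   identity_threshold: float = 60.0) -> list[tuple[str, str, float]]:
    """Reciprocal-best-hit ortholog pairing by global aa identity."""

    def best_hits(src: dict[str, str], dst: dict[str, str]) -> dict[str, tuple[str, float]]:
        out = {}
        for qa, sa in src.items():
            scored = [(global_align(sa, sb, "aa").identity_pct, qb)
                      for qb, sb in dst.items()]
            if scored:
                ident, qb = max(scored, key=lambda t: (t[0], t[1]))
                out[qa] = (qb, ident)
        return out

    fwd = best_hits(orfs_a, orfs_b)
    rev = best_hits(orfs_b, orfs_a)
    pairs = []
    for qa, (qb, ident) in fwd.items():
        if ident >= identity_threshold and rev.get(qb, (None,))[0] == qa:
            pairs.append((qa, qb, round(ident, 1)))
    return sorted(pairs)
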