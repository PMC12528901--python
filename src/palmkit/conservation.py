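"""Sequence conservation: pairwise identity, rank tests and trees.

Percent identity between ortholog pairs is computed from an optimal
pairwise alignment (global Needleman-Wunsch or local Smith-Waterman under
BLOSUM62 with affine gaps, blastp-default costs 11/1).  Identity feeds two
summaries: ortholog panel statistics (median/range/mean/SD) compared
between binder and non-binder groups with a two-tailed Mann-Whitney U
test, and a 100-minus-identity distance matrix clustered into an unrooted
tree by neighbor joining (Saitou-Nei, Q-criterion).  No evolutionary
distance correction is applied to identities before tree building.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices
from scipy import stats as _stats
from skbio.tree import TreeNode

from .io import AnalysisConfig, ProteinRecord

logger = logging.getLogger("palmkit")


# ---------------------------------------------------------------------------
# Pairwise alignment and identity
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PairwiseAlignment:
    """An optimal pairwise alignment.

    ``aligned_a``/``aligned_b`` are equal-length strings with ``-`` gaps;
    for local mode they cover only the aligned region of each input.
    ``matches`` counts identical aligned columns, ``columns`` the alignment
    length.
    """

    aligned_a: str
    aligned_b: str
    score: float
    mode: str = "global"

    def __post_init__(self) -> None:
        if len(self.aligned_a) != len(self.aligned_b):
            raise ValueError("aligned strings must have equal length")

    @property
    def columns(self) -> int:
        return len(self.aligned_a)

    @property
    def matches(self) -> int:
        return sum(
            x == y and x != "-"
            for x, y in zip(self.aligned_a, self.aligned_b)
        )


def _make_aligner(
    mode: str, matrix: str, gap_open: float, gap_extend: float
) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = mode
    aligner.substitution_matrix = substitution_matrices.load(matrix)
    # blastp convention: a length-L gap costs gap_open + gap_extend * L
    aligner.open_gap_score = -(gap_open + gap_extend)
    aligner.extend_gap_score = -gap_extend
    return aligner


def align_pair(
    a: str,
    b: str,
    mode: str = "global",
    matrix: str = "BLOSUM62",
    gap_open: float = 11.0,
    gap_extend: float = 1.0,
) -> PairwiseAlignment:
    """Optimal global or local alignment of two protein sequences.

    Ties between co-optimal alignments are broken deterministically by
    taking the first alignment in the aligner's fixed enumeration order.
    """
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    if mode not in ("global", "local"):
        raise ValueError("mode must be 'global' or 'local'")
    aligner = _make_aligner(mode, matrix, gap_open, gap_extend)
    aln = aligner.align(a, b)[0]
    return PairwiseAlignment(
        aligned_a=str(aln[0]), aligned_b=str(aln[1]), score=aln.score, mode=mode
    )


def percent_identity(
    aln: PairwiseAlignment, convention: str = "columns",
    seq_a: str | None = None, seq_b: str | None = None,
) -> float:
    """Percent identity of an alignment, in [0, 100].

    ``"columns"`` divides matches by alignment length (NCBI convention);
    ``"shorter"`` divides by the length of the shorter input sequence
    (pass the original sequences for local alignments, where the aligned
    strings cover only part of each input).
    """
    if aln.columns == 0:
        raise ValueError("zero-column alignment has no identity")
    if convention == "columns":
        return 100.0 * aln.matches / aln.columns
    if convention == "shorter":
        la = len(seq_a) if seq_a is not None else len(aln.aligned_a.replace("-", ""))
        lb = len(seq_b) if seq_b is not None else len(aln.aligned_b.replace("-", ""))
        return 100.0 * aln.matches / min(la, lb)
    raise ValueError("convention must be 'columns' or 'shorter'")


def pair_identity(
    a: ProteinRecord | str,
    b: ProteinRecord | str,
    config: AnalysisConfig | None = None,
) -> float:
    """Convenience: align two sequences under *config* and return identity."""
    config = config or AnalysisConfig()
    sa = a.sequence if isinstance(a, ProteinRecord) else a
    sb = b.sequence if isinstance(b, ProteinRecord) else b
    aln = align_pair(
        sa,
        sb,
        mode=config.alignment_mode,
        matrix=config.substitution_matrix,
        gap_open=config.gap_open,
        gap_extend=config.gap_extend,
    )
    return percent_identity(aln, config.identity_convention, sa, sb)


def ortholog_identity_stats(
    pairs: Sequence[tuple[ProteinRecord, ProteinRecord]],
    config: AnalysisConfig | None = None,
) -> dict:
    """Summary statistics of per-pair percent identity.

    Median uses the midpoint of the central pair for even counts; SD is the
    sample standard deviation (ddof=1, NaN for a single pair).
    """
    if not pairs:
        raise ValueError("at least one pair required")
    idents = np.array([pair_identity(a, b, config) for a, b in pairs])
    return {
        "identities": idents.tolist(),
        "median": float(np.median(idents)),
        "min": float(idents.min()),
        "max": float(idents.max()),
        "mean": float(idents.mean()),
        "sd": float(idents.std(ddof=1)) if len(idents) > 1 else float("nan"),
        "n": len(idents),
    }


# ---------------------------------------------------------------------------
# Mann-Whitney U
# ---------------------------------------------------------------------------

def _u_statistic(a: Sequence[float], b: Sequence[float]) -> float:
    """U for group A: #(a>b) pairs + 0.5 * #(a==b) pairs."""
    return sum(
        1.0 if x > y else (0.5 if x == y else 0.0) for x in a for y in b
    )


def mann_whitney_u(
    group_a: Sequence[float], group_b: Sequence[float]
) -> dict:
    """Two-tailed Mann-Whitney U test.

    For combined sample sizes of at most 12 with no ties across the pooled
    data, the p-value is exact: the null distribution of U is enumerated
    over all ways of partitioning the pooled values into groups of the
    observed sizes.  Otherwise a normal approximation with tie and
    continuity corrections is used.  ``method`` reports which path ran.
    Returns U for the first group.
    """
    a, b = list(group_a), list(group_b)
    if not a or not b:
        raise ValueError("both groups must be non-empty")
    pooled = a + b
    if len(set(pooled)) == 1:
        logger.warning("all values identical across both groups; p = 1")
        return {"U": _u_statistic(a, b), "p": 1.0, "method": "degenerate"}
    has_ties = len(set(pooled)) < len(pooled)
    if len(pooled) <= 12 and not has_ties:
        u_obs = _u_statistic(a, b)
        n_ab = len(a) * len(b)
        # two-tailed: mass at least as extreme as u_obs on either tail
        lo, hi = min(u_obs, n_ab - u_obs), max(u_obs, n_ab - u_obs)
        count = total = 0
        for combo in itertools.combinations(range(len(pooled)), len(a)):
            sel = set(combo)
            u = _u_statistic(
                [pooled[i] for i in sel],
                [pooled[i] for i in range(len(pooled)) if i not in sel],
            )
            total += 1
            if u <= lo or u >= hi:
                count += 1
        return {"U": u_obs, "p": count / total, "method": "exact"}
    res = _stats.mannwhitneyu(
        a, b, alternative="two-sided", method="asymptotic", use_continuity=True
    )
    return {"U": float(res.statistic), "p": float(res.pvalue), "method": "asymptotic"}


# ---------------------------------------------------------------------------
# Distance matrix and neighbor joining
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric distances with a zero diagonal over ordered labels."""

    labels: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "labels", tuple(self.labels))
        object.__setattr__(self, "values", vals)
        n = len(self.labels)
        if vals.shape != (n, n):
            raise ValueError(f"matrix shape {vals.shape} != ({n}, {n})")
        if not np.allclose(vals, vals.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(vals), 0.0):
            raise ValueError("distance matrix diagonal must be zero")
        if (vals < -1e-12).any():
            raise ValueError("distance matrix entries must be non-negative")

    def __getitem__(self, pair: tuple[str, str]) -> float:
        i = self.labels.index(pair[0])
        j = self.labels.index(pair[1])
        return float(self.values[i, j])


def identity_distance_matrix(
    records: Sequence[ProteinRecord], config: AnalysisConfig | None = None
) -> DistanceMatrix:
    """Pairwise distance 100 - percent identity, one alignment per pair."""
    if len(records) < 3:
        raise ValueError("need at least 3 records")
    n = len(records)
    vals = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = 100.0 - pair_identity(records[i], records[j], config)
            vals[i, j] = vals[j, i] = max(d, 0.0)
    return DistanceMatrix(labels=tuple(r.id for r in records), values=vals)


def neighbor_joining(dm: DistanceMatrix) -> TreeNode:
    """Saitou-Nei neighbor joining on the Q-criterion.

    Joins the minimal-Q pair at each step (ties broken by the lowest
    label-index pair in row-major order); branch lengths that come out
    negative are clamped to zero with the deficit logged.  The result is an
    unrooted binary tree represented with a trifurcating root node.
    """
    n = len(dm.labels)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    d = dm.values.astype(float).copy()
    nodes: list[TreeNode] = [TreeNode(name=lab) for lab in dm.labels]
    active = list(range(n))

    def clamp(length: float) -> float:
        if length < 0:
            logger.debug("clamping negative branch length %.6g to 0", length)
            return 0.0
        return length

    while len(active) > 3:
        m = len(active)
        r = {i: sum(d[i, j] for j in active if j != i) for i in active}
        best = None
        for ai, i in enumerate(active):
            for j in active[ai + 1 :]:
                q = (m - 2) * d[i, j] - r[i] - r[j]
                if best is None or q < best[0] - 1e-12:
                    best = (q, i, j)
        _, i, j = best
        li = clamp(d[i, j] / 2 + (r[i] - r[j]) / (2 * (m - 2)))
        lj = clamp(d[i, j] - (d[i, j] / 2 + (r[i] - r[j]) / (2 * (m - 2))))
        nodes[i].length = li
        nodes[j].length = lj
        parent = TreeNode(children=[nodes[i], nodes[j]])
        # reuse slot i for the new node; grow the matrix by mapping onto it
        new_row = np.zeros(d.shape[0])
        for k in active:
            if k in (i, j):
                continue
            new_row[k] = (d[i, k] + d[j, k] - d[i, j]) / 2
        d[i, :] = new_row
        d[:, i] = new_row
        nodes[i] = parent
        active.remove(j)

    # connect the last three nodes through a central (root) node
    i, j, k = active
    li = clamp((d[i, j] + d[i, k] - d[j, k]) / 2)
    lj = clamp((d[i, j] + d[j, k] - d[i, k]) / 2)
    lk = clamp((d[i, k] + d[j, k] - d[i, j]) / 2)
    nodes[i].length = li
    nodes[j].length = lj
    nodes[k].length = lk
    return TreeNode(children=[nodes[i], nodes[j], nodes[k]])


def is_clade(tree: TreeNode, taxa: Iterable[str]) -> bool:
    """True iff some edge bipartition separates exactly *taxa* from the rest.

    Operates on the unrooted topology: both sides of every internal edge
    are checked, so a set forming either half of a split counts.
    """
    taxa = set(taxa)
    leaves = {t.name for t in tree.tips()}
    unknown = taxa - leaves
    if unknown:
        raise ValueError(f"unknown taxa: {sorted(unknown)}")
    if len(taxa) in (1, len(leaves)):
        return True
    for node in tree.non_tips(include_self=False):
        side = {t.name for t in node.tips()}
        if side == taxa or leaves - side == taxa:
            return True
    # leaf edges also induce bipartitions (complement of a singleton)
    if len(taxa) == len(leaves) - 1:
        return any(leaves - {t.name} == taxa for t in tree.tips())
    return False


def tree_to_newick(tree: TreeNode, decimals: int = 6) -> str:
    """Newick string with fixed-format branch lengths (byte-stable)."""

    def render(node: TreeNode) -> str:
        if node.is_tip():
            body = node.name or ""
        else:
            body = "(" + ",".join(render(c) for c in node.children) + ")"
            if node.name:
                body += node.name
        if node.length is not None:
            body += f":{node.length:.{decimals}f}"
        return body

    return render(tree) + ";"
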