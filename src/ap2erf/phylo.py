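"""Unrooted neighbor-joining trees with bootstrap support.

Distances are pairwise-deletion p-distances: for each sequence pair,
alignment columns containing a gap in either sequence are dropped and
the distance is the fraction of mismatching retained columns. Trees are
built with the Saitou-Nei neighbor-joining algorithm (Q criterion) with
deterministic tie-breaking, and edge support is estimated by resampling
alignment columns with replacement.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from skbio import TreeNode

from ._align import make_aligner


@dataclass
class DistanceMatrix:
    """Symmetric distance matrix over named taxa."""

    ids: tuple[str, ...]
    matrix: np.ndarray
    method: str = "pairwise-deletion"

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (len(self.ids), len(self.ids)):
            raise ValueError("matrix shape does not match taxa")
        if not np.all(np.isfinite(m)):
            raise ValueError("distances must be finite")
        if not np.allclose(m, m.T):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(m), 0):
            raise ValueError("diagonal must be zero")
        if (m < 0).any():
            raise ValueError("distances must be non-negative")
        self.matrix = m

    def to_tsv(self, path) -> None:
        pd.DataFrame(self.matrix, index=self.ids, columns=self.ids).to_csv(
            path, sep="\t")


@dataclass
class NJTree:
    tree: TreeNode
    negative_branches_clamped: int = 0
    supports: dict[frozenset, float] | None = None

    def to_newick(self) -> str:
        buf = io.StringIO()
        self.tree.write(buf, format="newick")
        return buf.getvalue().strip()


def pairwise_distances(
    sequences: Mapping[str, str],
    aligner=None,
) -> DistanceMatrix:
    """All-pairs global alignment p-distances with pairwise deletion."""
    ids = tuple(sequences)
    if len(ids) < 3:
        raise ValueError("need >= 3 sequences")
    if aligner is None:
        aligner = make_aligner()
    n = len(ids)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            a, b = sequences[ids[i]], sequences[ids[j]]
            aln = aligner.align(a, b)[0]
            counts = aln.counts()
            retained = counts.identities + counts.mismatches
            d[i, j] = d[j, i] = (counts.mismatches / retained) if retained else 0.0
    return DistanceMatrix(ids=ids, matrix=d)


def msa_p_distances(msa: Mapping[str, str],
                    columns: np.ndarray | None = None) -> DistanceMatrix:
    """Pairwise-deletion p-distances from a multiple alignment.

    ``columns`` optionally selects (with repetition) the alignment
    columns to use — the bootstrap resampling hook.
    """
    ids = tuple(msa)
    if len(ids) < 3:
        raise ValueError("need >= 3 sequences")
    length = len(next(iter(msa.values())))
    if any(len(msa[i]) != length for i in ids):
        raise ValueError("alignment is ragged")
    arr = np.array([list(msa[i]) for i in ids])
    if columns is not None:
        arr = arr[:, columns]
    gap = (arr == "-") | (arr == ".")
    n = len(ids)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            keep = ~(gap[i] | gap[j])
            retained = int(keep.sum())
            if retained == 0:
                raise ValueError(
                    f"no gap-free columns shared by {ids[i]} and {ids[j]}")
            mism = int((arr[i, keep] != arr[j, keep]).sum())
            d[i, j] = d[j, i] = mism / retained
    return DistanceMatrix(ids=ids, matrix=d)


def _min_leaf(node: TreeNode) -> str:
    if node.is_tip():
        return node.name
    return min(_min_leaf(c) for c in node.children)


def neighbor_joining(dm: DistanceMatrix) -> NJTree:
    """Saitou-Nei neighbor joining with deterministic tie-breaking.

    At each step the pair minimizing Q = (n-2) d_ij - r_i - r_j is
    joined; ties break to the pair whose (smallest-leaf, smallest-leaf)
    label pair sorts first. Negative branch-length estimates are clamped
    to zero and counted.
    """
    n = len(dm.ids)
    if n < 3:
        raise ValueError("neighbor joining needs >= 3 taxa")
    nodes: list[TreeNode] = [TreeNode(name=i) for i in dm.ids]
    labels = [i for i in dm.ids]          # smallest leaf under each node
    d = dm.matrix.copy()
    clamped = 0

    def clamp(x: float) -> float:
        nonlocal clamped
        if x < 0:
            clamped += 1
            return 0.0
        return x

    while len(nodes) > 3:
        m = len(nodes)
        r = d.sum(axis=1)
        best = None
        for i in range(m):
            for j in range(i + 1, m):
                q = (m - 2) * d[i, j] - r[i] - r[j]
                tie = tuple(sorted((labels[i], labels[j])))
                key = (q, tie)
                if best is None or key < best[0]:
                    best = (key, i, j)
        _, i, j = best
        li = 0.5 * d[i, j] + (r[i] - r[j]) / (2 * (m - 2))
        lj = d[i, j] - li
        new = TreeNode(children=[nodes[i], nodes[j]])
        nodes[i].length = clamp(li)
        nodes[j].length = clamp(lj)
        # distances from the new node to all others
        du = 0.5 * (d[i, :] + d[j, :] - d[i, j])
        keep = [k for k in range(m) if k not in (i, j)]
        d_new = np.zeros((m - 1, m - 1))
        d_new[:-1, :-1] = d[np.ix_(keep, keep)]
        d_new[-1, :-1] = d_new[:-1, -1] = du[keep]
        d = d_new
        new_label = min(labels[i], labels[j])
        nodes = [nodes[k] for k in keep] + [new]
        labels = [labels[k] for k in keep] + [new_label]

    # terminal 3-star: closed-form branch lengths
    a, b, c = nodes
    la = 0.5 * (d[0, 1] + d[0, 2] - d[1, 2])
    lb = 0.5 * (d[0, 1] + d[1, 2] - d[0, 2])
    lc = 0.5 * (d[0, 2] + d[1, 2] - d[0, 1])
    a.length, b.length, c.length = clamp(la), clamp(lb), clamp(lc)
    root = TreeNode(children=[a, b, c])
    if clamped:
        warnings.warn(f"{clamped} negative NJ branch length(s) clamped to 0")
    return NJTree(tree=root, negative_branches_clamped=clamped)


def bipartitions(tree: TreeNode) -> set[frozenset]:
    """Non-trivial bipartitions of an unrooted tree.

    Each internal edge is encoded by the side of the split not containing
    the lexicographically smallest leaf, so the encoding is orientation-
    free and comparable across trees on the same taxa.
    """
    leaves = sorted(t.name for t in tree.tips())
    anchor = leaves[0]
    out: set[frozenset] = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if len(side) < 2 or len(side) > len(leaves) - 2:
            continue
        if anchor in side:
            side = frozenset(leaves) - side
        out.add(side)
    return out


def bootstrap_support(
    msa: Mapping[str, str],
    n_reps: int = 1000,
    seed: int = 0,
) -> NJTree:
    """NJ tree from a multiple alignment with bootstrap edge supports.

    Alignment columns are resampled with replacement ``n_reps`` times
    (one shared column index per replicate, applied to every pairwise
    comparison); support is the percentage of replicate trees containing
    each internal bipartition of the original tree.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    base = neighbor_joining(msa_p_distances(msa))
    targets = bipartitions(base.tree)
    hits = {bp: 0 for bp in targets}
    rng = np.random.default_rng(seed)
    length = len(next(iter(msa.values())))
    for _ in range(n_reps):
        cols = rng.integers(0, length, size=length)
        rep_tree = neighbor_joining(msa_p_distances(msa, columns=cols)).tree
        rep_bps = bipartitions(rep_tree)
        for bp in targets:
            if bp in rep_bps:
                hits[bp] += 1
    supports = {bp: 100.0 * k / n_reps for bp, k in hits.items()}
    # annotate internal nodes with supports for newick output
    leaves = sorted(t.name for t in base.tree.tips())
    anchor = leaves[0]
    for node in base.tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if anchor in side:
            side = frozenset(leaves) - side
        if side in supports:
            node.name = f"{supports[side]:.0f}"
    base.supports = supports
    return base
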