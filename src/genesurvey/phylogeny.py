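"""Distance-based phylogeny of OTU archetype sequences.

Jukes-Cantor distances from the aligned window region feed a standard
neighbor-joining agglomeration; the result is an unrooted tree (represented
with a trifurcating root) with non-negative branch lengths, written as
Newick.  On an additive (four-point-condition) distance matrix NJ recovers
the generating tree exactly, branch lengths included — the key correctness
property the tests lean on.
"""

from __future__ import annotations

import warnings

import numpy as np
from skbio import DistanceMatrix, TreeNode

from .consensus_window import Alignment

DEFAULT_MAX_DISTANCE = 5.0


def jc_distance(
    alignment: Alignment, max_distance: float = DEFAULT_MAX_DISTANCE
) -> DistanceMatrix:
    """Pairwise Jukes-Cantor distances over shared non-gap columns.

    d = -(3/4) ln(1 - (4/3) p) with p the mismatch fraction across columns
    where both rows have a base.  Saturated pairs (p >= 3/4, where the
    formula diverges) are capped at ``max_distance`` with a warning; a pair
    sharing fewer than 2 columns is an error.
    """
    ids = list(alignment.rows)
    mat = np.array([np.frombuffer(s.encode(), dtype=np.uint8)
                    for s in alignment.rows.values()])
    nongap = mat != ord("-")
    n = len(ids)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            shared = nongap[i] & nongap[j]
            n_shared = int(shared.sum())
            if n_shared < 2:
                raise ValueError(
                    f"rows {ids[i]!r} and {ids[j]!r} share fewer than 2 columns"
                )
            p = float((mat[i, shared] != mat[j, shared]).mean())
            if p >= 0.75:
                warnings.warn(
                    f"saturated pair ({ids[i]!r}, {ids[j]!r}): p={p:.3f}, "
                    f"capping distance at {max_distance}",
                    stacklevel=2,
                )
                dist = max_distance
            else:
                dist = min(-0.75 * np.log1p(-4.0 * p / 3.0), max_distance)
            d[i, j] = d[j, i] = dist
    return DistanceMatrix(d, ids=ids)


def neighbor_joining(dm: DistanceMatrix) -> TreeNode:
    """Standard neighbor joining; returns an unrooted tree as a TreeNode.

    Negative branch-length estimates (possible on non-additive input) are
    clamped to zero.  Deterministic: ties in the Q criterion go to the
    smallest index pair.
    """
    n = dm.shape[0]
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    d = dm.data.astype(float).copy()
    nodes = [TreeNode(name=i) for i in dm.ids]
    while len(nodes) > 3:
        m = len(nodes)
        totals = d.sum(axis=1)
        q = (m - 2) * d - totals[:, None] - totals[None, :]
        np.fill_diagonal(q, np.inf)
        i, j = np.unravel_index(int(q.argmin()), q.shape)  # row-major: smallest pair
        if i > j:
            i, j = j, i
        li = 0.5 * d[i, j] + (totals[i] - totals[j]) / (2.0 * (m - 2))
        lj = d[i, j] - li
        nodes[i].length = max(li, 0.0)
        nodes[j].length = max(lj, 0.0)
        parent = TreeNode(children=[nodes[i], nodes[j]])
        dk = 0.5 * (d[i] + d[j] - d[i, j])
        keep = [k for k in range(m) if k not in (i, j)]
        d_new = np.empty((m - 1, m - 1))
        d_new[:-1, :-1] = d[np.ix_(keep, keep)]
        d_new[-1, :-1] = d_new[:-1, -1] = dk[keep]
        d_new[-1, -1] = 0.0
        d = d_new
        nodes = [nodes[k] for k in keep] + [parent]
    # final trifurcation
    la = 0.5 * (d[0, 1] + d[0, 2] - d[1, 2])
    lb = 0.5 * (d[0, 1] + d[1, 2] - d[0, 2])
    lc = 0.5 * (d[0, 2] + d[1, 2] - d[0, 1])
    for node, length in zip(nodes, (la, lb, lc)):
        node.length = max(length, 0.0)
    return TreeNode(children=nodes)


def write_newick(tree: TreeNode, path) -> None:
    tree.write(str(path), format="newick")


def tree_distances(tree: TreeNode) -> DistanceMatrix:
    """Patristic tip-to-tip distances implied by a tree."""
    return tree.tip_tip_distances()
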