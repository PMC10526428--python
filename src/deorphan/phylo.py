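"""Distance-based tree inference and branch support.

Neighbor joining (Saitou–Nei, with the standard Studier–Keppler
Q-matrix), nonparametric bootstrap support by alignment-column
resampling (Felsenstein), outgroup rooting, and a long-branch flag.

Determinism contracts
---------------------
* NJ tie-break: among equal-Q pairs, the smallest (i, j) pair in the
  current node order (newly joined nodes are appended at the end).
* Negative NJ branch lengths are clamped to zero and the deficit moved
  to the sister branch, preserving their sum.
* Bootstrap replicate ``r`` draws its columns from a generator seeded
  with ``(seed, r)``, so replicates are order-independent.
* Support is ``100 * count / n_reps`` rounded to the nearest integer,
  ties rounding up, so strict thresholds like ">70" are well defined.
"""
from __future__ import annotations

import math
from collections import Counter
from statistics import median
from typing import Optional

import numpy as np

from .pairwise import AlignmentMatrix, DistanceMatrix, msa_distances
from .tree import Node, PhyloTree


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def neighbor_joining(D: DistanceMatrix) -> PhyloTree:
    """Classic neighbor joining on a symmetric distance matrix.

    Returns an unrooted tree (trifurcating virtual root). Requires at
    least three taxa. On an additive matrix the generating topology is
    recovered exactly.
    """
    n = D.n
    if n < 3:
        raise ValueError("neighbor joining requires at least 3 taxa")
    d = D.d.copy()
    nodes: list[Node] = [Node(name=i) for i in D.ids]

    while len(nodes) > 3:
        m = len(nodes)
        r = d.sum(axis=1)
        Q = (m - 2) * d - r[:, None] - r[None, :]
        # only i < j; row-major argmin gives the smallest (i, j) tie-break
        mask = np.triu(np.ones((m, m), dtype=bool), k=1)
        Q = np.where(mask, Q, np.inf)
        flat = int(np.argmin(Q))
        i, j = divmod(flat, m)
        dij = d[i, j]
        li = 0.5 * dij + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = dij - li
        # clamp negatives, transferring the deficit to the sister branch
        if li < 0.0:
            lj += li
            li = 0.0
        if lj < 0.0:
            li += lj
            lj = 0.0
        li, lj = max(li, 0.0), max(lj, 0.0)
        parent = Node()
        ci, cj = nodes[i], nodes[j]
        ci.length, cj.length = li, lj
        parent.add_child(ci)
        parent.add_child(cj)
        dnew = 0.5 * (d[i, :] + d[j, :] - dij)
        keep = [k for k in range(m) if k not in (i, j)]
        d = np.vstack([
            np.hstack([d[np.ix_(keep, keep)], dnew[keep][:, None]]),
            np.hstack([dnew[keep][None, :], [[0.0]]]),
        ])
        nodes = [nodes[k] for k in keep] + [parent]

    # final three nodes joined at the trifurcating virtual root
    (a, b, c) = nodes
    dab, dac, dbc = d[0, 1], d[0, 2], d[1, 2]
    la = max(0.5 * (dab + dac - dbc), 0.0)
    lb = max(0.5 * (dab + dbc - dac), 0.0)
    lc = max(0.5 * (dac + dbc - dab), 0.0)
    root = Node()
    for node, length in ((a, la), (b, lb), (c, lc)):
        node.length = length
        root.add_child(node)
    return PhyloTree(root, rooted=False)


def bootstrap_support(
    msa: AlignmentMatrix,
    n_reps: int = 100,
    seed: int = 0,
    correction: str = "poisson",
) -> PhyloTree:
    """NJ point tree with nonparametric bootstrap supports.

    Builds the point-estimate NJ tree from the full alignment, then for
    each of ``n_reps`` replicates resamples columns with replacement,
    recomputes distances and the NJ tree, and counts bipartitions. Each
    internal edge of the point tree gets support
    ``100 * occurrences / n_reps`` (rounded, ties up).
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    if msa.length < 1:
        raise ValueError("alignment has no columns")
    point = neighbor_joining(msa_distances(msa, correction))
    counts: Counter = Counter()
    length = msa.length
    for rep in range(n_reps):
        rng = np.random.default_rng([int(seed), rep])
        cols = rng.integers(0, length, size=length)
        rep_tree = neighbor_joining(msa_distances(msa, correction, columns=cols))
        counts.update(rep_tree.bipartitions())

    full = frozenset(point.leaf_names())
    ref = min(full)
    lsm = point.leafset_map()
    for node in point.preorder():
        if node is point.root or node.is_leaf:
            continue
        side = lsm[node] if ref not in lsm[node] else full - lsm[node]
        if 2 <= len(side) <= len(full) - 2:
            node.support = _round_half_up(100.0 * counts[side] / n_reps)
    return point


def root_with_outgroup(tree: PhyloTree, outgroup_id: str) -> PhyloTree:
    """Root a tree on the branch subtending the outgroup leaf.

    The root is placed at the midpoint of the outgroup's terminal
    branch; all leaf-to-leaf path lengths are preserved and every edge
    support stays attached to the same bipartition.
    """
    out_leaf = tree.find_leaf(outgroup_id)  # KeyError if absent
    if out_leaf.parent is None:
        raise ValueError("outgroup leaf is the tree root")

    # undirected adjacency with per-edge (length, support)
    nodes = list(tree.preorder())
    adj: dict = {id(n): [] for n in nodes}
    src: dict = {id(n): n for n in nodes}
    for n in nodes:
        if n.parent is None:
            continue
        length = n.length if n.length is not None else 0.0
        support = None if n.is_leaf else n.support
        adj[id(n)].append((id(n.parent), length, support))
        adj[id(n.parent)].append((id(n), length, support))

    def build(nid: int, came_from: int, length: Optional[float], support) -> Node:
        orig = src[nid]
        node = Node(name=orig.name if orig.is_leaf else None,
                    length=length, support=support)
        for nbr, ln, sup in adj[nid]:
            if nbr == came_from:
                continue
            node.add_child(build(nbr, nid, ln, sup))
        return node

    half = (out_leaf.length if out_leaf.length is not None else 0.0) / 2.0
    root = Node()
    root.add_child(Node(name=out_leaf.name, length=half))
    root.add_child(build(id(out_leaf.parent), id(out_leaf), half, None))

    def suppress(node: Node) -> Node:
        # a degree-2 former root becomes a unifurcation; merge its edges
        for k, child in enumerate(node.children):
            node.children[k] = suppress(child)
            node.children[k].parent = node
        if len(node.children) == 1 and node.parent is not None:
            child = node.children[0]
            child.length = (child.length or 0.0) + (node.length or 0.0)
            if child.support is None:
                child.support = node.support
            return child
        return node

    root = suppress(root)
    return PhyloTree(root, rooted=True)


def unroot(tree: PhyloTree) -> PhyloTree:
    """Collapse a bifurcating root into a trifurcation (inverse of rooting)."""
    if not tree.rooted:
        return tree.copy()
    t = tree.copy()
    root = t.root
    if len(root.children) != 2:
        return PhyloTree(root, rooted=False)
    a, b = root.children
    keep, merge = (a, b) if not a.is_leaf else (b, a)
    if keep.is_leaf:
        raise ValueError("cannot unroot a two-leaf tree")
    merge.length = (merge.length or 0.0) + (keep.length or 0.0)
    new_root = Node()
    for child in keep.children:
        new_root.add_child(child)
    new_root.add_child(merge)
    return PhyloTree(new_root, rooted=False)


def flag_long_branches(tree: PhyloTree, k: float = 3.0) -> list:
    """Leaves whose terminal branch exceeds ``k`` times the median terminal branch.

    A crude screen for candidate long-branch-attraction artifacts.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    leaves = tree.leaves()
    if len(leaves) < 2:
        raise ValueError("need at least two leaves")
    lengths = {leaf.name: (leaf.length or 0.0) for leaf in leaves}
    med = median(lengths.values())
    return sorted(name for name, ln in lengths.items() if ln > k * med)
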