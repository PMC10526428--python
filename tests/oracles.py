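"""Independent brute-force oracles used by the test suite.

Each oracle recomputes an expected result by a route deliberately
different from the implementation it checks:

* exhaustive enumeration of all affine-gap global alignments (tiny
  sequences) instead of dynamic programming;
* exhaustive enumeration of unrooted topologies with nonnegative
  least-squares branch fitting instead of neighbor joining;
* set-based clade enumeration instead of tree-walking label ascent.
"""
from __future__ import annotations

import itertools

import numpy as np

from deorphan.curation import ChemClass, Evidence, LigandLabel
from deorphan.pairwise import DistanceMatrix
from deorphan.tree import Node, PhyloTree


# ---------------------------------------------------------------------------
# alignment oracle
# ---------------------------------------------------------------------------

def brute_force_align_score(a, b, matrix, gap_open=11.0, gap_extend=1.0):
    """Maximum global alignment score by exhaustive path enumeration.

    Affine convention: a gap run of length L costs open + (L-1)*extend.
    Practical only for len(a), len(b) <= ~6.
    """
    neg_inf = float("-inf")

    def rec(i, j, prev):
        if i == len(a) and j == len(b):
            return 0.0
        best = neg_inf
        if i < len(a) and j < len(b):
            best = max(best, matrix[a[i], b[j]] + rec(i + 1, j + 1, "M"))
        if i < len(a):
            cost = gap_extend if prev == "D" else gap_open
            best = max(best, -cost + rec(i + 1, j, "D"))
        if j < len(b):
            cost = gap_extend if prev == "I" else gap_open
            best = max(best, -cost + rec(i, j + 1, "I"))
        return best

    return rec(0, 0, None)


# ---------------------------------------------------------------------------
# topology oracles
# ---------------------------------------------------------------------------

def enumerate_unrooted_topologies(taxa):
    """All unrooted binary topologies over ``taxa`` (3 for n=4, 15 for n=5)."""
    taxa = list(taxa)
    base = PhyloTree(Node(), rooted=False)
    for name in taxa[:3]:
        base.root.add_child(Node(name=name))
    trees = [base]
    for name in taxa[3:]:
        grown = []
        for tree in trees:
            edges = [n for n in tree.preorder() if n.parent is not None]
            for k in range(len(edges)):
                t2 = tree.copy()
                e2 = [n for n in t2.preorder() if n.parent is not None]
                child = e2[k]
                parent = child.parent
                mid = Node()
                parent.children[parent.children.index(child)] = mid
                mid.parent = parent
                mid.add_child(child)
                mid.add_child(Node(name=name))
                grown.append(PhyloTree(t2.root, rooted=False))
        trees = grown
    return trees


def least_squares_fit(tree, D: DistanceMatrix):
    """Nonnegative least-squares branch lengths for a fixed topology.

    Returns the sum of squared residuals of the best fit of path
    lengths to the matrix.
    """
    from scipy.optimize import nnls

    edges = [n for n in tree.preorder() if n.parent is not None]
    edge_index = {id(n): k for k, n in enumerate(edges)}
    leaf = {n.name: n for n in tree.leaves()}
    pairs = list(itertools.combinations(D.ids, 2))
    A = np.zeros((len(pairs), len(edges)))
    y = np.zeros(len(pairs))
    for row, (p, q) in enumerate(pairs):
        y[row] = D.value(p, q)
        # path via ancestor chains
        anc_p = []
        node = leaf[p]
        while node.parent is not None:
            anc_p.append(node)
            node = node.parent
        on_p = {id(n) for n in anc_p}
        node = leaf[q]
        anc_q = []
        while node.parent is not None and id(node) not in on_p:
            anc_q.append(node)
            node = node.parent
        meet = id(node) if node.parent is not None else None
        for n in anc_q:
            A[row, edge_index[id(n)]] = 1.0
        for n in anc_p:
            if meet is not None and id(n) == meet:
                break
            A[row, edge_index[id(n)]] = 1.0
    x, _ = nnls(A, y)
    residual = A @ x - y
    return float(residual @ residual)


def best_topology_by_least_squares(taxa, D: DistanceMatrix):
    """Bipartition set of the minimum-SSE topology over all unrooted trees."""
    best_sse, best_tree = None, None
    for tree in enumerate_unrooted_topologies(taxa):
        sse = least_squares_fit(tree, D)
        if best_sse is None or sse < best_sse:
            best_sse, best_tree = sse, tree
    return best_tree.bipartitions(), best_sse


def random_additive_tree(rng, n_taxa, length_low=0.1, length_high=1.0):
    """A random unrooted binary tree with uniform branch lengths."""
    taxa = [f"t{i + 1}" for i in range(n_taxa)]
    trees = enumerate_unrooted_topologies(taxa[:3])
    tree = trees[0]
    for name in taxa[3:]:
        edges = [n for n in tree.preorder() if n.parent is not None]
        child = edges[int(rng.integers(0, len(edges)))]
        parent = child.parent
        mid = Node()
        parent.children[parent.children.index(child)] = mid
        mid.parent = parent
        mid.add_child(child)
        mid.add_child(Node(name=name))
        tree = PhyloTree(tree.root, rooted=False)
    for node in tree.preorder():
        if node.parent is not None:
            node.length = float(rng.uniform(length_low, length_high))
    return tree


def additive_matrix(tree) -> DistanceMatrix:
    """Path-length distance matrix of a tree with branch lengths."""
    ids = sorted(tree.leaf_names())
    n = len(ids)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = tree.path_length(ids[i], ids[j])
    return DistanceMatrix(ids, d)


# ---------------------------------------------------------------------------
# propagation oracle
# ---------------------------------------------------------------------------

def oracle_propagate(tree: PhyloTree, labels, s_prop, exclude=()):
    """Set-based reimplementation of clade label propagation.

    Enumerates every clade of the rooted tree as a plain tip set and
    applies the acceptance predicate (support strictly above the
    threshold, no conflicting experimental label) by subset inspection —
    no parent pointers, no ascent. Clades below the threshold are simply
    not accepted; the smallest threshold-clearing clade that contains a
    conflict blocks everything above it. Returns
    ``{tip: (evidence, name, min_support)}`` where ``name`` is the
    ligand (or the chemical class for class-level entries) and
    ``min_support`` is None for experimental/orphan tips.
    """
    drop = set(exclude)
    lsm = tree.leafset_map()
    clades = [
        (frozenset(lsm[n] - drop), n.support)
        for n in tree.preorder() if not n.is_leaf
    ]
    tips = set(tree.leaf_names()) - drop
    exp = {t: l for t, l in labels.items() if t not in drop}

    def conflicting(clade, ligand):
        return any(s in exp and exp[s].ligand != ligand for s in clade)

    assigned: dict = {}
    class_clades = []
    for source in sorted(exp):
        ligand = exp[source].ligand
        chain = sorted(
            (c for c in clades if source in c[0]),
            key=lambda c: (len(c[0]), c[1] is None),
        )
        accepted = []
        blocked = None
        for clade, support in chain:
            if support is None or not support > s_prop:
                continue  # not a qualifying clade; look further up
            if conflicting(clade, ligand):
                blocked = (clade, support)
                break
            accepted.append((clade, support))
        if accepted:
            top = accepted[-1][0]
            min_support = min(s for _, s in accepted)
            for tip in top:
                if tip in exp:
                    continue
                prev = assigned.get(tip)
                if prev is None or min_support > prev[1]:
                    assigned[tip] = (ligand, min_support)
        if blocked is not None:
            clade, support = blocked
            for other in sorted(clade):
                if (
                    other in exp
                    and exp[other].ligand != ligand
                    and exp[other].chem_class == exp[source].chem_class
                    and exp[source].chem_class != ChemClass.UNKNOWN
                ):
                    class_clades.append((clade, support, exp[source].chem_class))

    result: dict = {}
    for tip in sorted(tips):
        if tip in exp:
            result[tip] = ("experimental", exp[tip].ligand, None)
        elif tip in assigned:
            ligand, min_support = assigned[tip]
            result[tip] = ("propagated", ligand, min_support)
    for clade, support, chem in sorted(
        class_clades, key=lambda e: (len(e[0]), sorted(e[0]))
    ):
        for tip in clade:
            if tip not in result:
                result[tip] = ("class_level", chem.value, support)
    for tip in sorted(tips):
        if tip not in result:
            result[tip] = ("orphan", "orphan", None)
    return result


LIGAND_POOL = (
    ("ADP/ATP", ChemClass.NUCLEOTIDE),
    ("NAD+", ChemClass.NUCLEOTIDE),
    ("glutathione", ChemClass.AMINO_ACID),
    ("glycine", ChemClass.AMINO_ACID),
    ("citrate", ChemClass.CARBOXYLATE),
)


def random_labeled_tree(rng, max_tips=12):
    """Random rooted binary tree with random supports and 1-3 experimental labels."""
    n_tips = int(rng.integers(4, max_tips + 1))
    nodes = [Node(name=f"t{i + 1}", length=1.0) for i in range(n_tips)]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        parent = Node(length=1.0)
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [parent]
    tree = PhyloTree(nodes[0], rooted=True)
    for node in tree.internal_nodes():
        if node is not tree.root:
            node.support = int(rng.integers(0, 101))
    n_labels = int(rng.integers(1, 4))
    tips = tree.leaf_names()
    chosen = rng.choice(len(tips), size=min(n_labels, len(tips)), replace=False)
    labels = {}
    for idx in chosen:
        ligand, chem = LIGAND_POOL[int(rng.integers(0, len(LIGAND_POOL)))]
        labels[tips[int(idx)]] = LigandLabel(ligand, chem, Evidence.EXPERIMENTAL)
    return tree, labels


def summarize_result(result):
    """Comparable view of a PropagationResult for oracle equivalence checks."""
    out = {}
    for tip, entry in result.entries.items():
        evidence = entry.label.evidence.value
        if evidence == "class_level":
            name = entry.label.chem_class.value
        elif evidence == "orphan":
            name = "orphan"
        else:
            name = entry.label.ligand
        out[tip] = (evidence, name, entry.min_support)
    return out
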