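"""Phylogenetic tree container with support-aware Newick round-tripping.

The container is deliberately small: nodes carry a branch length to
their parent and (internal nodes only) an integer bootstrap support in
0..100. An unrooted tree is stored with a trifurcating virtual root; a
rooted tree has a bifurcating root. Newick parsing is delegated to
dendropy; both the support-as-internal-label dialect
(``(A:1,(B:1,C:1)90:1);``) and the support-in-comment dialect are read,
and the label dialect is written.
"""
from __future__ import annotations

from pathlib import Path
from typing import Iterable, Iterator, Optional

import dendropy


class Node:
    """A tree node; ``length`` is the branch to the parent."""

    __slots__ = ("name", "length", "support", "children", "parent")

    def __init__(
        self,
        name: Optional[str] = None,
        length: Optional[float] = None,
        support: Optional[int] = None,
    ) -> None:
        self.name = name
        self.length = length
        self.support = support
        self.children: list["Node"] = []
        self.parent: Optional["Node"] = None

    def add_child(self, node: "Node") -> "Node":
        node.parent = self
        self.children.append(node)
        return node

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        kind = self.name if self.is_leaf else f"internal/{len(self.children)}"
        return f"<Node {kind} len={self.length} sup={self.support}>"


class PhyloTree:
    """A (un)rooted phylogeny over uniquely named leaves."""

    def __init__(self, root: Node, rooted: bool = False) -> None:
        self.root = root
        self.rooted = rooted
        names = self.leaf_names()
        if len(names) != len(set(names)):
            raise ValueError("leaf names must be unique")

    # ------------------------------------------------------------------
    # traversal
    # ------------------------------------------------------------------
    def preorder(self) -> Iterator[Node]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def postorder(self) -> Iterator[Node]:
        out = list(self.preorder())
        return iter(reversed(out))

    def leaves(self) -> list[Node]:
        return [n for n in self.preorder() if n.is_leaf]

    def leaf_names(self) -> list[str]:
        return [n.name for n in self.leaves()]

    def internal_nodes(self) -> list[Node]:
        return [n for n in self.preorder() if not n.is_leaf]

    def find_leaf(self, name: str) -> Node:
        for leaf in self.leaves():
            if leaf.name == name:
                return leaf
        raise KeyError(f"leaf {name!r} not in tree")

    def copy(self) -> "PhyloTree":
        def clone(node: Node) -> Node:
            new = Node(node.name, node.length, node.support)
            for child in node.children:
                new.add_child(clone(child))
            return new

        return PhyloTree(clone(self.root), rooted=self.rooted)

    # ------------------------------------------------------------------
    # clades and bipartitions
    # ------------------------------------------------------------------
    def leafset_map(self) -> dict:
        """Map node -> frozenset of descendant leaf names (nodes hashed by identity)."""
        out: dict = {}
        for node in self.postorder():
            if node.is_leaf:
                out[node] = frozenset([node.name])
            else:
                acc: set = set()
                for child in node.children:
                    acc |= out[child]
                out[node] = frozenset(acc)
        return out

    def _canonical(self, side: frozenset, full: frozenset, ref: str) -> frozenset:
        return side if ref not in side else full - side

    def bipartitions(self) -> set:
        """Nontrivial bipartitions as canonical frozensets of leaf names.

        The canonical side of each split is the one not containing the
        lexicographically smallest leaf; both sides must have >= 2 leaves.
        """
        return set(self.support_map().keys())

    def support_map(self) -> dict:
        """Map canonical bipartition -> support (int or None) of its edge."""
        full = frozenset(self.leaf_names())
        if len(full) < 4:
            return {}
        ref = min(full)
        lsm = self.leafset_map()
        out: dict = {}
        for node in self.preorder():
            if node is self.root or node.is_leaf:
                continue
            side = self._canonical(lsm[node], full, ref)
            if not (2 <= len(side) <= len(full) - 2):
                continue
            if side in out and out[side] is not None:
                continue  # complementary root-child edges: keep first non-None
            out[side] = node.support
        return out

    def has_clade(self, tips: Iterable[str]) -> bool:
        """True if ``tips`` is exactly the leaf set of some node (rooted sense)."""
        want = frozenset(tips)
        return any(s == want for s in self.leafset_map().values())

    # ------------------------------------------------------------------
    # path lengths
    # ------------------------------------------------------------------
    def path_length(self, a: str, b: str) -> float:
        """Sum of branch lengths along the path between leaves ``a`` and ``b``."""
        na, nb = self.find_leaf(a), self.find_leaf(b)

        def chain(node: Node):
            depth = {}
            total = 0.0
            while node is not None:
                depth[node] = total
                total += node.length or 0.0
                node = node.parent
            return depth

        da = chain(na)
        node, to_b = nb, 0.0
        while node is not None:
            if node in da:
                return da[node] + to_b
            to_b += node.length or 0.0
            node = node.parent
        raise ValueError("leaves are not connected")  # pragma: no cover

    # ------------------------------------------------------------------
    # Newick I/O
    # ------------------------------------------------------------------
    def to_newick(self, supports: bool = True, lengths: bool = True) -> str:
        def fmt(node: Node) -> str:
            if node.is_leaf:
                s = node.name or ""
            else:
                s = "(" + ",".join(fmt(c) for c in node.children) + ")"
                if node is not self.root:
                    if supports and node.support is not None:
                        s += str(int(node.support))
                    elif node.name:
                        s += node.name
            if lengths and node.length is not None and node is not self.root:
                s += f":{node.length:.10g}"
            return s

        return fmt(self.root) + ";"

    @classmethod
    def from_newick(cls, text: str, rooted: Optional[bool] = None) -> "PhyloTree":
        try:
            dtree = dendropy.Tree.get(
                data=text,
                schema="newick",
                suppress_internal_node_taxa=True,
                preserve_underscores=True,
            )
        except Exception as exc:
            raise ValueError(f"malformed Newick: {exc}") from exc

        def convert(dnode) -> Node:
            node = Node(length=dnode.edge.length)
            if dnode.is_leaf():
                if dnode.taxon is not None:
                    node.name = dnode.taxon.label
                elif dnode.label is not None:
                    node.name = dnode.label
            else:
                support = None
                if dnode.label is not None:
                    try:
                        support = int(round(float(dnode.label)))
                    except ValueError:
                        node.name = dnode.label
                if support is None:
                    for comment in dnode.comments or ():
                        try:
                            support = int(round(float(comment.strip("&"))))
                            break
                        except ValueError:
                            continue
                node.support = support
                for child in dnode.child_nodes():
                    node.add_child(convert(child))
            return node

        root = convert(dtree.seed_node)
        if rooted is None:
            rooted = len(root.children) == 2
        return cls(root, rooted=rooted)

    def write(self, path, supports: bool = True) -> None:
        Path(path).write_text(self.to_newick(supports=supports) + "\n")

    @classmethod
    def read(cls, path, rooted: Optional[bool] = None) -> "PhyloTree":
        return cls.from_newick(Path(path).read_text(), rooted=rooted)
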