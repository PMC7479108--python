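"""Lightweight rooted-tree container used across the pipeline.

Newick parsing/serialisation is delegated to dendropy; this module only
provides the in-memory node structure the numerical code operates on
(ages in million years, per-node events, species maps) plus the handful
of tree manipulations the pipeline needs (rerooting, MRCA, ultrametric
checks).  Branch identifiers are child-node labels throughout.
"""

from __future__ import annotations

import io
from typing import Callable, Iterator, Optional

import dendropy
import numpy as np

__all__ = ["Node", "Tree", "parse_newick", "to_newick"]


class Node:
    __slots__ = ("name", "length", "parent", "children", "age", "event",
                 "species", "support", "extra")

    def __init__(self, name: Optional[str] = None, length: float = 0.0):
        self.name = name
        self.length = length          # branch length to parent
        self.parent: Optional["Node"] = None
        self.children: list["Node"] = []
        self.age: Optional[float] = None   # MY before present (tips 0)
        self.event: Optional[str] = None   # 'S' | 'D' | 'R' for internals
        self.species: Optional[str] = None # tip -> species
        self.support: Optional[float] = None
        self.extra: dict = {}

    # -- structure ---------------------------------------------------------
    @property
    def is_leaf(self) -> bool:
        return not self.children

    def add_child(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    def remove_child(self, child: "Node") -> None:
        self.children.remove(child)
        child.parent = None

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        kind = "leaf" if self.is_leaf else f"{len(self.children)}ch"
        return f"<Node {self.name!r} {kind} len={self.length:.4g}>"


class Tree:
    """Rooted tree; root may be multifurcating only before explicit rooting."""

    def __init__(self, root: Node):
        self.root = root

    # -- traversals --------------------------------------------------------
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

    def internals(self) -> list[Node]:
        return [n for n in self.preorder() if not n.is_leaf]

    def leaf_names(self) -> list[str]:
        return [n.name for n in self.leaves()]

    def find(self, name: str) -> Node:
        for n in self.preorder():
            if n.name == name:
                return n
        raise KeyError(name)

    def __len__(self) -> int:
        return len(self.leaves())

    def copy(self) -> "Tree":
        def _clone(node: Node) -> Node:
            c = Node(node.name, node.length)
            c.age, c.event, c.species = node.age, node.event, node.species
            c.support = node.support
            c.extra = dict(node.extra)
            for ch in node.children:
                c.add_child(_clone(ch))
            return c
        return Tree(_clone(self.root))

    # -- labels ------------------------------------------------------------
    def canonical_order(self) -> None:
        """Sort children by their smallest descendant leaf name (stable)."""
        key: dict[int, str] = {}
        for node in self.postorder():
            if node.is_leaf:
                key[id(node)] = node.name or ""
            else:
                node.children.sort(key=lambda c: key[id(c)])
                key[id(node)] = key[id(node.children[0])]

    def label_internals(self, prefix: str = "n", overwrite: bool = False) -> None:
        """Deterministic internal labels: canonical order, then preorder index."""
        self.canonical_order()
        i = 0
        for node in self.preorder():
            if not node.is_leaf:
                if overwrite or not node.name:
                    node.name = f"{prefix}{i}"
                i += 1

    # -- metrics -----------------------------------------------------------
    def depths(self) -> dict[int, float]:
        """Root-to-node path lengths (sums of branch lengths)."""
        d = {id(self.root): 0.0}
        for node in self.preorder():
            if node is not self.root:
                d[id(node)] = d[id(node.parent)] + node.length
        return d

    def max_depth(self) -> float:
        d = self.depths()
        return max(d[id(leaf)] for leaf in self.leaves())

    def set_ages_from_lengths(self) -> None:
        """Ages = max root-to-tip depth minus node depth (ultrametric trees)."""
        d = self.depths()
        top = self.max_depth()
        for node in self.preorder():
            node.age = top - d[id(node)]

    def set_lengths_from_ages(self) -> None:
        for node in self.preorder():
            if node.parent is not None:
                node.length = node.parent.age - node.age

    def is_ultrametric(self, tol: float = 1e-6) -> bool:
        d = self.depths()
        tip_depths = [d[id(leaf)] for leaf in self.leaves()]
        return (max(tip_depths) - min(tip_depths)) < tol

    def mrca(self, names) -> Node:
        names = set(names)
        hit: dict[int, int] = {}
        best = None
        for node in self.postorder():
            if node.is_leaf:
                hit[id(node)] = 1 if node.name in names else 0
            else:
                hit[id(node)] = sum(hit[id(c)] for c in node.children)
            if hit[id(node)] == len(names):
                best = node
                break
        if best is None:
            raise KeyError(f"tips not all present: {sorted(names)}")
        return best

    def species_sets(self) -> dict[int, frozenset]:
        """Per-node set of tip species (falls back to tip names)."""
        out: dict[int, frozenset] = {}
        for node in self.postorder():
            if node.is_leaf:
                out[id(node)] = frozenset([node.species or node.name])
            else:
                acc: set = set()
                for c in node.children:
                    acc |= out[id(c)]
                out[id(node)] = frozenset(acc)
        return out

    # -- surgery -----------------------------------------------------------
    def suppress_unifurcations(self) -> None:
        changed = True
        while changed:
            changed = False
            for node in list(self.preorder()):
                if node.is_leaf or len(node.children) != 1:
                    continue
                child = node.children[0]
                if node.parent is None:
                    child.length = 0.0
                    child.parent = None
                    self.root = child
                else:
                    parent = node.parent
                    idx = parent.children.index(node)
                    child.length += node.length
                    child.parent = parent
                    parent.children[idx] = child
                changed = True

    def prune_leaf(self, leaf: Node) -> None:
        parent = leaf.parent
        if parent is None:
            raise ValueError("cannot prune the root")
        parent.remove_child(leaf)
        self.suppress_unifurcations()

    def edges(self) -> list[Node]:
        """Branches as child nodes (excludes the root's null branch)."""
        return [n for n in self.preorder() if n.parent is not None]

    def reroot_on_edge(self, child: Node, fraction: float = 0.5) -> "Tree":
        """Return a new tree rooted on the branch above `child`.

        `fraction` is the distance from `child` to the new root divided
        by the branch length.  The original tree is left untouched.
        """
        cp = self.copy()
        # locate the corresponding node in the copy via preorder index
        orig = list(self.preorder())
        idx = next(i for i, n in enumerate(orig) if n is child)
        target = list(cp.preorder())[idx]
        if target.parent is None:
            return cp
        old_parent = target.parent
        blen = target.length
        new_root = Node(None, 0.0)
        # detach target; hang it under the new root
        old_parent.remove_child(target)
        new_root.add_child(target)
        target.length = blen * fraction
        # walk from old_parent up to the old root, reversing parent links
        carry = blen * (1.0 - fraction)
        node = old_parent
        prev = new_root
        while node is not None:
            up = node.parent
            up_len = node.length
            if up is not None:
                up.remove_child(node)
            prev.add_child(node)
            node.length = carry
            carry = up_len
            prev = node
            node = up
        out = Tree(new_root)
        out.suppress_unifurcations()
        return out


# ---------------------------------------------------------------------------
# newick I/O (via dendropy)
# ---------------------------------------------------------------------------

def _from_dendropy(dtree: dendropy.Tree) -> Tree:
    def _conv(dnode) -> Node:
        if dnode.is_leaf():
            name = dnode.taxon.label if dnode.taxon is not None else dnode.label
        else:
            name = dnode.label
        n = Node(name, dnode.edge.length or 0.0)
        if not dnode.is_leaf() and dnode.label is not None:
            try:
                n.support = float(dnode.label)
            except ValueError:
                pass
        for ch in dnode.child_nodes():
            n.add_child(_conv(ch))
        return n
    return Tree(_conv(dtree.seed_node))


def parse_newick(newick: str) -> Tree:
    dtree = dendropy.Tree.get(data=newick, schema="newick",
                              preserve_underscores=True,
                              suppress_internal_node_taxa=True)
    return _from_dendropy(dtree)


def to_newick(tree: Tree, annotations: bool = False,
              digits: int = 17) -> str:
    """Serialise; with `annotations`, NHX-style comments carry per-node
    event/species/age metadata."""
    buf = io.StringIO()

    def _ann(node: Node) -> str:
        if not annotations:
            return ""
        parts = []
        if node.event:
            parts.append(f"Ev={node.event}")
        if node.species:
            parts.append(f"Sp={node.species}")
        if node.age is not None:
            parts.append(f"Age={node.age:.6g}")
        for k, v in sorted(node.extra.items()):
            parts.append(f"{k}={v}")
        return "[&&NHX:" + ":".join(parts) + "]" if parts else ""

    def _write(node: Node) -> None:
        if node.children:
            buf.write("(")
            for i, ch in enumerate(node.children):
                if i:
                    buf.write(",")
                _write(ch)
            buf.write(")")
        if node.name:
            buf.write(node.name)
        if node.parent is not None:
            buf.write(f":{node.length:.{digits}g}")
        buf.write(_ann(node))

    _write(tree.root)
    buf.write(";")
    return buf.getvalue()


def tip_trait_matrix(tree: Tree, traits) -> np.ndarray:
    """Order a {tip-name -> vector} mapping (or DataFrame) by tree tips."""
    import pandas as pd
    names = tree.leaf_names()
    if isinstance(traits, pd.DataFrame):
        return traits.loc[names].to_numpy(dtype=float)
    return np.asarray([traits[n] for n in names], dtype=float)
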