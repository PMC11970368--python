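"""Distance-based tree building: neighbor joining, UPGMA, Newick, consensus.

Neighbor joining follows Saitou & Nei with the Studier-Keppler Q-criterion

    Q(i, j) = (r - 2) D(i, j) - R_i - R_j,    R_i = sum_k D(i, k)

joining the pair with minimal Q (ties broken by the lexicographically
smallest index pair, for determinism), with branch lengths

    l_i = D(i,j)/2 + (R_i - R_j) / (2 (r - 2)),   l_j = D(i,j) - l_i

and distance update D(u, k) = (D(i,k) + D(j,k) - D(i,j)) / 2.  The final
three lineages are joined at an unrooted trifurcation.  Negative branch
lengths are kept as computed unless clamping is requested.

UPGMA performs cluster-size-weighted average-linkage agglomeration with
node heights D(merge)/2, producing a rooted ultrametric tree.

The majority-rule consensus collects non-trivial bipartitions across
replicate trees and keeps those whose frequency exceeds the threshold
(strict majority by default), attaching round(100 * frequency) as support.
"""

from __future__ import annotations

import re
from typing import Iterator, Sequence

import numpy as np

from .distance import DistanceMatrix
from .errors import NewickError, TreeError

__all__ = [
    "Node",
    "PhyloTree",
    "neighbor_joining",
    "upgma",
    "write_newick",
    "parse_newick",
    "majority_consensus",
]


class Node:
    """A tree node: leaf (has ``name``) or internal (has ``children``)."""

    __slots__ = ("name", "length", "support", "children", "parent")

    def __init__(self, name=None, length=None, support=None, children=None):
        self.name = name
        self.length = length
        self.support = support
        self.children: list[Node] = []
        self.parent: Node | None = None
        for child in children or []:
            self.add_child(child)

    def add_child(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        kind = f"leaf {self.name!r}" if self.is_leaf else f"internal({len(self.children)})"
        return f"<Node {kind} len={self.length}>"


class PhyloTree:
    """A rooted node structure; NJ trees carry a trifurcating root (unrooted)."""

    def __init__(self, root: Node):
        self.root = root

    def iter_nodes(self) -> Iterator[Node]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(node.children)

    def leaves(self) -> list[Node]:
        return [n for n in self.iter_nodes() if n.is_leaf]

    def leaf_names(self) -> tuple[str, ...]:
        # Stable left-to-right order.
        out: list[str] = []

        def walk(node: Node) -> None:
            if node.is_leaf:
                out.append(node.name)
            for c in node.children:
                walk(c)

        walk(self.root)
        return tuple(out)

    def bipartitions(self) -> set[frozenset]:
        """Non-trivial splits, each canonicalised as the side *excluding*
        the alphabetically first leaf (well defined for unrooted trees)."""
        all_leaves = frozenset(self.leaf_names())
        if len(all_leaves) != len(self.leaf_names()):
            raise TreeError("duplicate leaf names")
        ref = min(all_leaves)
        splits: set[frozenset] = set()

        def clade(node: Node) -> frozenset:
            if node.is_leaf:
                return frozenset([node.name])
            out: frozenset = frozenset()
            for c in node.children:
                out |= clade(c)
            return out

        for node in self.iter_nodes():
            if node is self.root or node.is_leaf:
                continue
            side = clade(node)
            if ref in side:
                side = all_leaves - side
            if 2 <= len(side) <= len(all_leaves) - 2:
                splits.add(side)
        return splits

    def leaf_depths(self) -> dict[str, float]:
        """Root-to-leaf path lengths (missing lengths count as 0)."""
        depths: dict[str, float] = {}

        def walk(node: Node, h: float) -> None:
            h += node.length or 0.0
            if node.is_leaf:
                depths[node.name] = h
            for c in node.children:
                walk(c, h)

        walk(self.root, -(self.root.length or 0.0))
        return depths

    def pairwise_path_lengths(self) -> DistanceMatrix:
        """Leaf-to-leaf path-length matrix (the additive distances)."""
        names = self.leaf_names()
        index = {n: i for i, n in enumerate(names)}
        n = len(names)
        D = np.zeros((n, n))

        def walk(node: Node) -> dict[int, float]:
            if node.is_leaf:
                below = {index[node.name]: 0.0}
            else:
                below = {}
                child_maps = [walk(c) for c in node.children]
                for a in range(len(child_maps)):
                    for b in range(a + 1, len(child_maps)):
                        for i, di in child_maps[a].items():
                            for j, dj in child_maps[b].items():
                                D[i, j] = D[j, i] = di + dj
                for cm in child_maps:
                    below.update(cm)
            return {i: d + (node.length or 0.0) for i, d in below.items()}

        walk(self.root)
        return DistanceMatrix(names, D)

    def clamp_negative_lengths(self) -> None:
        for node in self.iter_nodes():
            if node.length is not None and node.length < 0:
                node.length = 0.0

    def newick(self, decimals: int = 6) -> str:
        return write_newick(self, decimals)


def _check_matrix(dm: DistanceMatrix, min_n: int) -> np.ndarray:
    if dm.n < min_n:
        raise TreeError(f"need at least {min_n} samples, got {dm.n}")
    dm.require_defined()
    return dm.values.copy()


def neighbor_joining(dm: DistanceMatrix, clamp_negative: bool = False) -> PhyloTree:
    """Saitou-Nei NJ; O(n^3); returns an unrooted tree (trifurcating root)."""
    D = _check_matrix(dm, 3)
    nodes = [Node(name=n) for n in dm.names]
    while len(nodes) > 3:
        r = len(nodes)
        R = D.sum(axis=1)
        Q = (r - 2) * D - R[:, None] - R[None, :]
        # Lexicographic tie-break: mask the diagonal and lower triangle, then
        # take the first row-major minimum.
        Q[np.tril_indices(r)] = np.inf
        i, j = np.unravel_index(np.argmin(Q), Q.shape)
        dij = D[i, j]
        li = 0.5 * dij + (R[i] - R[j]) / (2.0 * (r - 2))
        lj = dij - li
        nodes[i].length = li
        nodes[j].length = lj
        parent = Node(children=[nodes[i], nodes[j]])
        # Distances from the new node to everyone else.
        du = 0.5 * (D[i, :] + D[j, :] - dij)
        keep = [k for k in range(r) if k not in (i, j)]
        newD = np.empty((r - 1, r - 1))
        newD[:-1, :-1] = D[np.ix_(keep, keep)]
        newD[-1, :-1] = du[keep]
        newD[:-1, -1] = du[keep]
        newD[-1, -1] = 0.0
        D = newD
        nodes = [nodes[k] for k in keep] + [parent]
    # Join the last three lineages at a trifurcation.
    (a, b, c) = nodes
    a.length = 0.5 * (D[0, 1] + D[0, 2] - D[1, 2])
    b.length = 0.5 * (D[0, 1] + D[1, 2] - D[0, 2])
    c.length = 0.5 * (D[0, 2] + D[1, 2] - D[0, 1])
    tree = PhyloTree(Node(children=[a, b, c]))
    if clamp_negative:
        tree.clamp_negative_lengths()
    return tree


def upgma(dm: DistanceMatrix) -> PhyloTree:
    """Average-linkage agglomeration; rooted, ultrametric; O(n^3)."""
    D = _check_matrix(dm, 2)
    nodes = [Node(name=n) for n in dm.names]
    heights = [0.0] * len(nodes)
    sizes = np.ones(len(nodes))
    while len(nodes) > 1:
        r = len(nodes)
        M = D.copy()
        M[np.tril_indices(r)] = np.inf
        i, j = np.unravel_index(np.argmin(M), M.shape)
        h = D[i, j] / 2.0
        nodes[i].length = h - heights[i]
        nodes[j].length = h - heights[j]
        parent = Node(children=[nodes[i], nodes[j]])
        si, sj = sizes[i], sizes[j]
        du = (si * D[i, :] + sj * D[j, :]) / (si + sj)
        keep = [k for k in range(r) if k not in (i, j)]
        newD = np.empty((r - 1, r - 1))
        newD[:-1, :-1] = D[np.ix_(keep, keep)]
        newD[-1, :-1] = du[keep]
        newD[:-1, -1] = du[keep]
        newD[-1, -1] = 0.0
        D = newD
        nodes = [nodes[k] for k in keep] + [parent]
        heights = [heights[k] for k in keep] + [h]
        sizes = np.append(sizes[keep], si + sj)
    return PhyloTree(nodes[0])


# ---------------------------------------------------------------------------
# Newick

_NEEDS_QUOTE = re.compile(r"[\s()\[\]{}:;,\"']")


def _format_label(name: str) -> str:
    if name and not _NEEDS_QUOTE.search(name):
        return name
    return "'" + name.replace("'", "''") + "'"


def _format_length(length: float | None, decimals: int) -> str:
    if length is None:
        return ""
    return f":{length:.{decimals}f}"


def write_newick(tree: PhyloTree, decimals: int = 6) -> str:
    """Serialise to Newick; internal supports become internal node labels."""

    def render(node: Node) -> str:
        if node.is_leaf:
            return _format_label(node.name or "") + _format_length(node.length, decimals)
        inner = ",".join(render(c) for c in node.children)
        label = ""
        if node.support is not None:
            sup = node.support
            label = str(int(sup)) if float(sup).is_integer() else f"{sup:g}"
        elif node.name:
            label = _format_label(node.name)
        return f"({inner}){label}" + _format_length(node.length, decimals)

    return render(tree.root) + ";"


class _NewickParser:
    def __init__(self, text: str):
        self.text = text
        self.pos = 0

    def error(self, msg: str) -> NewickError:
        return NewickError(f"Newick parse error at offset {self.pos}: {msg}")

    def peek(self) -> str:
        while self.pos < len(self.text) and self.text[self.pos].isspace():
            self.pos += 1
        return self.text[self.pos] if self.pos < len(self.text) else ""

    def take(self) -> str:
        ch = self.peek()
        self.pos += 1
        return ch

    def parse(self) -> Node:
        node = self.parse_node()
        if self.peek() != ";":
            raise self.error("expected ';'")
        self.take()
        if self.peek():
            raise self.error("trailing content after ';'")
        return node

    def parse_node(self) -> Node:
        if self.peek() == "(":
            self.take()
            node = Node()
            node.add_child(self.parse_node())
            while self.peek() == ",":
                self.take()
                node.add_child(self.parse_node())
            if self.peek() != ")":
                raise self.error("expected ')' or ','")
            self.take()
            label = self.parse_label()
            if label:
                try:
                    node.support = float(label)
                except ValueError:
                    node.name = label
        else:
            label = self.parse_label()
            node = Node(name=label if label else None)
            if node.name is None:
                raise self.error("expected a leaf label")
        if self.peek() == ":":
            self.take()
            node.length = self.parse_number()
        return node

    def parse_label(self) -> str:
        if self.peek() == "'":
            self.take()
            out = []
            while True:
                if self.pos >= len(self.text):
                    raise self.error("unterminated quoted label")
                ch = self.text[self.pos]
                self.pos += 1
                if ch == "'":
                    if self.pos < len(self.text) and self.text[self.pos] == "'":
                        out.append("'")
                        self.pos += 1
                    else:
                        break
                else:
                    out.append(ch)
            return "".join(out)
        out = []
        self.peek()  # skip leading whitespace
        while self.pos < len(self.text) and self.text[self.pos] not in "(),:;'":
            out.append(self.text[self.pos])
            self.pos += 1
        return "".join(out).strip()

    def parse_number(self) -> float:
        start = self.pos
        self.peek()
        while self.pos < len(self.text) and (
            self.text[self.pos].isdigit() or self.text[self.pos] in "+-.eE"
        ):
            self.pos += 1
        token = self.text[start : self.pos].strip()
        try:
            return float(token)
        except ValueError:
            raise self.error(f"bad branch length {token!r}") from None


def parse_newick(text: str) -> PhyloTree:
    """Parse a single Newick tree; tolerant of missing branch lengths."""
    return PhyloTree(_NewickParser(text).parse())


# ---------------------------------------------------------------------------
# majority-rule consensus


def majority_consensus(
    trees: Sequence[PhyloTree], threshold: float = 0.5
) -> PhyloTree:
    """Strict-majority consensus over replicate trees with support values.

    Keeps every non-trivial bipartition with frequency strictly above
    ``threshold`` (must be in [0.5, 1]); such splits are pairwise compatible
    by the pigeonhole argument, so they nest into a tree.  Supports are
    round(100 * frequency); branch lengths are not assigned.
    """
    if len(trees) < 2:
        raise TreeError("consensus needs at least 2 trees")
    if not 0.5 <= threshold <= 1.0:
        raise TreeError("consensus threshold must be in [0.5, 1]")
    leafsets = [frozenset(t.leaf_names()) for t in trees]
    base = leafsets[0]
    for k, ls in enumerate(leafsets[1:], start=2):
        if ls != base:
            diff = sorted(ls ^ base)
            raise TreeError(f"tree {k} leaf set differs from tree 1: {', '.join(diff)}")
    counts: dict[frozenset, int] = {}
    for t in trees:
        for split in t.bipartitions():
            counts[split] = counts.get(split, 0) + 1
    n_trees = len(trees)
    retained = {
        split: cnt / n_trees
        for split, cnt in counts.items()
        if cnt / n_trees > threshold
    }
    # Nest retained splits (all exclude the reference leaf, so they are plain
    # sets that either nest or are disjoint).
    ordered = sorted(retained, key=len, reverse=True)
    full = base
    parent_of: dict[frozenset, frozenset] = {}
    placed: list[frozenset] = [full]
    for s in ordered:
        parent_of[s] = min((p for p in placed if s <= p), key=len)
        placed.append(s)
    children_sets: dict[frozenset, list[frozenset]] = {full: []}
    for s in ordered:
        children_sets.setdefault(s, [])
        children_sets[parent_of[s]].append(s)

    def build(s: frozenset) -> Node:
        node = Node()
        if s is not full:
            node.support = round(100.0 * retained[s])
        covered: set = set()
        for sub in children_sets[s]:
            node.add_child(build(sub))
            covered |= sub
        for leaf in sorted(s - covered):
            node.add_child(Node(name=leaf))
        return node

    return PhyloTree(build(full))
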