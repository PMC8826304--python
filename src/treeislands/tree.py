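"""Unrooted leaf-labelled tree topologies.

A :class:`Tree` stores an unrooted topology as an adjacency map between
integer node ids. Leaves carry taxon labels from a shared
:class:`~treeislands.taxa.TaxonIndex`; internal nodes are anonymous and must
have degree >= 3 (polytomies allowed, degree-2 vertices are suppressed at
construction). Branch lengths are deliberately absent: every downstream
computation in this package is purely topological.
"""

from __future__ import annotations

from collections.abc import Iterator

from .errors import ArgumentError, ValidationError
from .taxa import TaxonIndex

__all__ = ["Tree", "canonical_mask"]


def canonical_mask(mask: int, full_mask: int) -> int:
    """Canonical form of a bipartition bit-vector: the side whose bit for
    taxon 0 is clear. Two branches induce the same split iff their canonical
    masks are equal."""
    return mask ^ full_mask if mask & 1 else mask


class Tree:
    """An unrooted topology over a fixed taxon universe.

    Parameters
    ----------
    index
        The shared taxon universe; the tree's leaves must carry exactly
        these labels.
    adj
        Adjacency map ``node id -> set of neighbour ids``.
    leaf_label
        Map from leaf node id to taxon label.
    """

    __slots__ = ("index", "adj", "leaf_label", "label_node")

    def __init__(self, index: TaxonIndex, adj: dict[int, set[int]],
                 leaf_label: dict[int, str], validate: bool = True):
        self.index = index
        self.adj = adj
        self.leaf_label = leaf_label
        self.label_node = {lab: node for node, lab in leaf_label.items()}
        if validate:
            self._validate()

    # ------------------------------------------------------------------ #
    # structure

    def _validate(self) -> None:
        nodes = set(self.adj)
        if not nodes:
            raise ValidationError("empty tree")
        n_edges = sum(len(v) for v in self.adj.values())
        if n_edges % 2:
            raise ValidationError("asymmetric adjacency")
        n_edges //= 2
        if n_edges != len(nodes) - 1:
            raise ValidationError("tree must be acyclic and connected "
                                  f"({len(nodes)} nodes, {n_edges} edges)")
        # connectivity
        seen = set()
        stack = [next(iter(nodes))]
        while stack:
            u = stack.pop()
            if u in seen:
                continue
            seen.add(u)
            stack.extend(self.adj[u] - seen)
        if seen != nodes:
            raise ValidationError("tree is disconnected")
        for u, nbrs in self.adj.items():
            deg = len(nbrs)
            if deg == 1:
                if u not in self.leaf_label:
                    raise ValidationError(f"unlabelled leaf node {u}")
            elif deg == 2 and len(nodes) > 2:
                raise ValidationError(f"internal node {u} has degree 2 "
                                      "(unrooted trees keep degree >= 3)")
            elif u in self.leaf_label:
                raise ValidationError(f"labelled node {u} has degree {deg}")
        labels = set(self.leaf_label.values())
        if len(labels) != len(self.leaf_label):
            raise ValidationError("repeated leaf label")
        expected = set(self.index.labels)
        if labels != expected:
            missing = sorted(expected - labels)
            extra = sorted(labels - expected)
            raise ValidationError(
                f"leaf set does not match taxon universe: missing={missing}, extra={extra}")

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_label)

    def degree(self, node: int) -> int:
        return len(self.adj[node])

    def edges(self) -> Iterator[tuple[int, int]]:
        """All edges as ordered pairs (u, v) with u < v."""
        for u, nbrs in self.adj.items():
            for v in nbrs:
                if u < v:
                    yield (u, v)

    def internal_edges(self) -> list[tuple[int, int]]:
        """Edges whose both endpoints are internal nodes."""
        return [(u, v) for u, v in self.edges()
                if u not in self.leaf_label and v not in self.leaf_label]

    def is_binary(self) -> bool:
        return all(len(nbrs) in (1, 3) for nbrs in self.adj.values())

    def copy(self) -> "Tree":
        return Tree(self.index, {u: set(v) for u, v in self.adj.items()},
                    dict(self.leaf_label), validate=False)

    def new_node_id(self) -> int:
        return max(self.adj) + 1

    # ------------------------------------------------------------------ #
    # split machinery

    def subtree_masks(self, root: int) -> dict[int, int]:
        """Leaf-set bit-vector below every node when the tree is rooted at
        ``root`` (the root's own mask is the full universe)."""
        pos = self.index.positions
        order: list[tuple[int, int]] = []  # (node, parent)
        stack = [(root, -1)]
        while stack:
            u, p = stack.pop()
            order.append((u, p))
            for v in self.adj[u]:
                if v != p:
                    stack.append((v, u))
        masks: dict[int, int] = {}
        for u, p in reversed(order):
            if u in self.leaf_label:
                masks[u] = 1 << pos[self.leaf_label[u]]
            else:
                m = 0
                for v in self.adj[u]:
                    if v != p:
                        m |= masks[v]
                masks[u] = m
        return masks

    def split_masks(self) -> frozenset[int]:
        """Canonical bit-vectors of all nontrivial splits (one per internal
        edge; both sides >= 2 taxa)."""
        full = self.index.full_mask
        root = next(iter(self.adj))
        masks = self.subtree_masks(root)
        out = set()
        for u, p in self._parents(root).items():
            if p is None:
                continue
            m = masks[u]  # side of edge (p, u) away from root
            k = m.bit_count()
            if 2 <= k <= self.index.n - 2:
                out.add(canonical_mask(m, full))
        return frozenset(out)

    def edge_masks_from(self, root_node: int) -> dict[tuple[int, int], int]:
        """For every edge, the leaf bit-vector of the side *away* from
        ``root_node``, keyed by (nearer endpoint, farther endpoint)."""
        masks = self.subtree_masks(root_node)
        out = {}
        parent = self._parents(root_node)
        for u, p in parent.items():
            if p is not None:
                out[(p, u)] = masks[u]
        return out

    def _parents(self, root: int) -> dict[int, int | None]:
        parent: dict[int, int | None] = {root: None}
        stack = [root]
        while stack:
            u = stack.pop()
            for v in self.adj[u]:
                if v not in parent:
                    parent[v] = u
                    stack.append(v)
        return parent

    # ------------------------------------------------------------------ #
    # local edits (used by I/O and the synthetic generator)

    def attach_leaf(self, edge: tuple[int, int], label: str) -> int:
        """Subdivide ``edge`` with a new internal node and hang a new leaf
        carrying ``label`` from it (in place). Returns the new leaf id.

        The label must already be part of the taxon universe; callers that
        grow the universe build a new Tree via the constructor instead.
        """
        u, v = edge
        if v not in self.adj[u]:
            raise ArgumentError(f"({u}, {v}) is not an edge")
        w = self.new_node_id()
        leaf = w + 1
        self.adj[u].remove(v)
        self.adj[v].remove(u)
        self.adj[w] = {u, v, leaf}
        self.adj[u].add(w)
        self.adj[v].add(w)
        self.adj[leaf] = {w}
        self.leaf_label[leaf] = label
        self.label_node[label] = leaf
        return leaf

    def __eq__(self, other) -> bool:
        """Topology-level equality: same taxon universe, same split set."""
        return (isinstance(other, Tree) and self.index == other.index
                and self.split_masks() == other.split_masks())

    def __hash__(self) -> int:
        return hash((self.index, self.split_masks()))

    def __repr__(self) -> str:
        return f"Tree(n_leaves={self.n_leaves}, n_splits={len(self.split_masks())})"


def suppress_degree_two(adj: dict[int, set[int]], leaf_label: dict[int, str]) -> None:
    """Remove every degree-2 vertex from an adjacency map in place,
    reconnecting its two neighbours (standard unrooted normalization of a
    rooted binary encoding)."""
    changed = True
    while changed:
        changed = False
        for u in list(adj):
            if len(adj[u]) == 2 and u not in leaf_label and len(adj) > 2:
                a, b = adj[u]
                adj[a].discard(u)
                adj[b].discard(u)
                adj[a].add(b)
                adj[b].add(a)
                del adj[u]
                changed = True
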