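"""Bipartition algebra: split extraction, Robinson-Foulds distances,
split (clade) support frequencies, and majority-rule consensus.

A bipartition is stored as a canonical bit-vector over taxon positions
(the side not containing taxon 0), which makes split identity a single
integer comparison and the RF distance a symmetric difference of integer
sets. The unweighted RF distance between two trees is the size of the
symmetric difference of their nontrivial split sets; its normalized form
divides by the total number of nontrivial splits in the two trees (the
fraction of branches in one tree whose bipartition is absent from the
other), which handles unequally resolved trees with no extra convention.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ArgumentError, ValidationError
from .taxa import TaxonIndex
from .tree import Tree, canonical_mask
from .tree_io import TreeSample

__all__ = ["Bipartition", "DistanceMatrix", "tree_splits", "rf_distance",
           "rf_matrix", "split_frequencies", "majority_rule_consensus",
           "splits_compatible", "tree_from_clades"]


@dataclass(frozen=True)
class Bipartition:
    """A canonical two-way split of the taxon universe.

    ``mask`` has the bit of taxon 0 clear; ``n`` is the universe size.
    Nontrivial means both sides contain at least two taxa.
    """

    mask: int
    n: int

    @property
    def size(self) -> int:
        return self.mask.bit_count()

    @property
    def is_nontrivial(self) -> bool:
        return 2 <= self.size <= self.n - 2

    def sides(self, index: TaxonIndex) -> tuple[tuple[str, ...], tuple[str, ...]]:
        full = index.full_mask
        return index.labels_of(self.mask), index.labels_of(self.mask ^ full)

    def notation(self, index: TaxonIndex) -> str:
        """Human-readable ``A B C | D E`` form (taxon-0 side second)."""
        inside, outside = self.sides(index)
        return " ".join(inside) + " | " + " ".join(outside)


@dataclass
class DistanceMatrix:
    """Symmetric pairwise tree-distance matrix with tree provenance."""

    values: np.ndarray
    metric_name: str = "rf_proportion"
    tree_ids: list[str] = field(default_factory=list)
    analysis_labels: list[str] = field(default_factory=list)

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValidationError("distance matrix must be square")
        if not np.allclose(v, v.T):
            raise ValidationError("distance matrix must be symmetric")
        if np.any(np.diag(v) != 0):
            raise ValidationError("distance matrix diagonal must be zero")
        if np.any(v < 0):
            raise ValidationError("distances must be non-negative")
        if self.metric_name == "rf_proportion" and np.any(v > 1 + 1e-12):
            raise ValidationError("rf_proportion distances must be <= 1")
        self.values = v
        if not self.tree_ids:
            self.tree_ids = [f"tree_{i}" for i in range(v.shape[0])]

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def to_csv(self, path: str) -> None:
        df = pd.DataFrame(self.values, index=self.tree_ids, columns=self.tree_ids)
        df.to_csv(path)


# --------------------------------------------------------------------- #

def tree_splits(tree: Tree) -> frozenset[Bipartition]:
    """All nontrivial bipartitions of ``tree``, one per internal edge.

    For a fully resolved (binary) unrooted tree this has exactly n - 3
    elements; a star tree has none.
    """
    if tree.index.n < 4:
        raise ArgumentError("nontrivial splits require at least 4 taxa")
    n = tree.index.n
    return frozenset(Bipartition(m, n) for m in tree.split_masks())


def _check_same_index(a: Tree, b: Tree) -> None:
    if a.index != b.index:
        raise ValidationError("trees do not share a taxon universe")


def rf_distance(a: Tree, b: Tree, normalized: bool = True) -> float:
    """Unweighted Robinson-Foulds distance between two trees.

    ``normalized=False`` returns the raw symmetric-difference count;
    ``normalized=True`` divides by the summed split counts of both trees
    (0 when both trees are stars, so identical stars are at distance 0).
    """
    _check_same_index(a, b)
    sa, sb = a.split_masks(), b.split_masks()
    count = len(sa ^ sb)
    if not normalized:
        return float(count)
    denom = len(sa) + len(sb)
    return count / denom if denom else 0.0


def rf_matrix(sample: TreeSample, normalized: bool = True) -> DistanceMatrix:
    """Pairwise RF distances for a sample; split sets are computed once
    per tree so the pairwise stage is pure set arithmetic."""
    if len(sample) == 0:
        raise ArgumentError("empty sample")
    split_sets = [t.split_masks() for t in sample.trees]
    sizes = [len(s) for s in split_sets]
    t = len(split_sets)
    values = np.zeros((t, t))
    for i in range(t):
        si = split_sets[i]
        for j in range(i + 1, t):
            count = len(si ^ split_sets[j])
            if normalized:
                denom = sizes[i] + sizes[j]
                d = count / denom if denom else 0.0
            else:
                d = float(count)
            values[i, j] = values[j, i] = d
    return DistanceMatrix(values=values,
                          metric_name="rf_proportion" if normalized else "rf_count",
                          tree_ids=[f"tree_{i}" for i in range(t)],
                          analysis_labels=list(sample.tree_labels))


def split_frequencies(sample: TreeSample) -> dict[Bipartition, float]:
    """Frequency of every observed nontrivial split across the sample —
    the posterior probability of the corresponding clade when the sample
    is a post-burnin posterior."""
    if len(sample) == 0:
        raise ArgumentError("empty sample")
    n = sample.index.n
    counts: Counter[int] = Counter()
    for t in sample.trees:
        counts.update(t.split_masks())
    total = len(sample)
    return {Bipartition(m, n): c / total for m, c in counts.items()}


def export_split_frequencies(freqs: dict[Bipartition, float], index: TaxonIndex,
                             path: str) -> None:
    """TSV export in ``A B C | D E`` notation, descending frequency."""
    rows = sorted(freqs.items(), key=lambda kv: (-kv[1], kv[0].mask))
    with open(path, "w") as fh:
        fh.write("split\tfrequency\n")
        for bp, f in rows:
            fh.write(f"{bp.notation(index)}\t{f:.6g}\n")


# --------------------------------------------------------------------- #
# consensus

def splits_compatible(a: int, b: int, full: int) -> bool:
    """Two splits are compatible iff some pair of opposite sides is disjoint."""
    return (a & b == 0 or a & (b ^ full) == 0
            or (a ^ full) & b == 0 or (a ^ full) & (b ^ full) == 0)


def tree_from_clades(index: TaxonIndex, clade_masks: list[int]) -> Tree:
    """Build a Tree from a pairwise-compatible set of canonical split masks
    (treated as clusters relative to taxon 0) plus the implicit star."""
    full = index.full_mask
    clusters = sorted({m for m in clade_masks}, key=lambda m: -m.bit_count())
    for i, a in enumerate(clusters):
        for b in clusters[i + 1:]:
            if not splits_compatible(a, b, full):
                raise ValidationError("clade masks are not pairwise compatible")
    # rooted view: taxon 0 is the outgroup; every canonical mask is a cluster
    node_of: dict[int, int] = {}
    adj: dict[int, set[int]] = {}
    leaf_label: dict[int, str] = {}
    next_id = 0

    def new_node() -> int:
        nonlocal next_id
        adj[next_id] = set()
        next_id += 1
        return next_id - 1

    root = new_node()
    root_mask = full ^ 1  # everything but taxon 0
    node_of[root_mask] = root
    leaf0 = new_node()
    leaf_label[leaf0] = index.labels[0]
    adj[root].add(leaf0)
    adj[leaf0].add(root)

    parents: dict[int, int] = {}  # cluster mask -> node id of its parent cluster
    ordered = [m for m in clusters if m != root_mask]
    for m in ordered:
        # smallest already-placed cluster strictly containing m
        best = root_mask
        for c in ordered:
            if c != m and m & c == m and c.bit_count() > m.bit_count():
                if best == root_mask or c.bit_count() < best.bit_count():
                    best = c
        if best != root_mask and best not in node_of:
            continue  # parent placed later in ordered-by-size scan; cannot happen
        node = new_node()
        node_of[m] = node
        p = node_of[best]
        adj[p].add(node)
        adj[node].add(p)
        parents[m] = p
    # attach each remaining leaf to the smallest cluster containing it
    placed = sorted(node_of, key=lambda m: m.bit_count())
    for i in range(1, index.n):
        bit = 1 << i
        host = next(m for m in placed if m & bit)
        leaf = new_node()
        leaf_label[leaf] = index.labels[i]
        adj[node_of[host]].add(leaf)
        adj[leaf].add(node_of[host])
    from .tree import suppress_degree_two
    suppress_degree_two(adj, leaf_label)
    return Tree(index, adj, leaf_label)


def majority_rule_consensus(sample: TreeSample) -> tuple[Tree, dict[Bipartition, float]]:
    """Majority-rule consensus: the tree containing exactly the splits with
    frequency strictly greater than 0.5, plus each retained split's
    frequency (splits at exactly 0.5 are excluded; majority splits are
    pairwise compatible by a counting argument, so the tree exists)."""
    freqs = split_frequencies(sample)
    majority = {bp: f for bp, f in freqs.items() if f > 0.5}
    tree = tree_from_clades(sample.index, [bp.mask for bp in majority])
    return tree, majority
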