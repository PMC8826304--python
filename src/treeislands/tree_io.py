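"""Reading and writing tree samples.

Input formats are the ones Bayesian MCMC and parsimony programs emit:
plain Newick lists (one ';'-terminated tree per entry) and NEXUS trees
blocks, including the MrBayes ``.t`` dialect with a translate table and
``[&U]``/``[&R]`` rooting comments. Parsing is delegated to dendropy;
every parsed tree is normalized to the package's unrooted
:class:`~treeislands.tree.Tree` (degree-2 roots suppressed, branch lengths
and internal labels discarded) and bound to a shared taxon universe.

Burnin is applied per file, before any pooling: the first
``floor(burnin * T)`` of the ``T`` trees on file are discarded.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import dendropy

from .errors import ArgumentError, NewickParseError, ValidationError
from .taxa import TaxonIndex
from .tree import Tree, canonical_mask, suppress_degree_two

__all__ = ["TreeSample", "parse_newick", "read_tree_sample", "pool_samples",
           "write_newick", "write_newick_list"]

FORMATS = ("newick-list", "nexus")


@dataclass
class TreeSample:
    """A labelled, provenance-tagged list of topologies on one taxon universe.

    ``tree_labels`` records, per tree, the analysis it came from; after
    :func:`pool_samples` these differ while ``analysis_label`` names the pool.
    """

    trees: list[Tree]
    analysis_label: str
    burnin_applied: float = 0.0
    source_path: str = ""
    tree_labels: list[str] = field(default_factory=list)

    def __post_init__(self):
        if not self.analysis_label:
            raise ValidationError("analysis_label must be non-empty")
        if not self.tree_labels:
            self.tree_labels = [self.analysis_label] * len(self.trees)
        if len(self.tree_labels) != len(self.trees):
            raise ValidationError("tree_labels length must match trees")
        if self.trees:
            idx = self.trees[0].index
            for t in self.trees:
                if t.index != idx:
                    raise ValidationError("all trees in a sample must share one taxon universe")

    @property
    def index(self) -> TaxonIndex:
        if not self.trees:
            raise ArgumentError("empty tree sample")
        return self.trees[0].index

    def __len__(self) -> int:
        return len(self.trees)

    def __iter__(self):
        return iter(self.trees)


# --------------------------------------------------------------------- #
# parsing

def _dendropy_to_tree(dtree: dendropy.Tree, index: TaxonIndex | None) -> Tree:
    ids: dict = {}
    adj: dict[int, set[int]] = {}
    leaf_label: dict[int, str] = {}
    for i, nd in enumerate(dtree.preorder_node_iter()):
        ids[id(nd)] = i
        adj[i] = set()
    for nd in dtree.preorder_node_iter():
        u = ids[id(nd)]
        for ch in nd.child_nodes():
            v = ids[id(ch)]
            adj[u].add(v)
            adj[v].add(u)
    for nd in dtree.leaf_node_iter():
        u = ids[id(nd)]
        label = nd.taxon.label if nd.taxon is not None else (nd.label or "")
        label = str(label).strip()
        if not label:
            raise ValidationError("leaf without a label")
        leaf_label[u] = label
    suppress_degree_two(adj, leaf_label)
    if index is None:
        index = TaxonIndex(sorted(leaf_label.values()))
    return Tree(index, adj, leaf_label)


def parse_newick(text: str, index: TaxonIndex | None = None) -> Tree:
    """Parse one Newick string into an unrooted :class:`Tree`.

    Rooted (degree-2 root) and unrooted encodings of the same topology
    yield the same stored tree; branch lengths and internal-node labels
    are parsed but ignored. If ``index`` is given the leaf labels are
    validated against it, otherwise a sorted index is built from the tree.
    """
    stripped = text.strip()
    if not stripped.endswith(";"):
        raise NewickParseError(
            f"Newick string must end with ';' (character offset {len(text)})")
    try:
        dtree = dendropy.Tree.get(data=stripped, schema="newick",
                                  preserve_underscores=True,
                                  suppress_internal_node_taxa=True)
    except Exception as exc:  # dendropy's parse errors carry line/column info
        raise NewickParseError(f"malformed Newick: {exc}") from None
    return _dendropy_to_tree(dtree, index)


def read_tree_sample(path: str, format: str = "newick-list",
                     burnin: float = 0.0, label: str = "sample") -> TreeSample:
    """Read a tree-sample file, apply burnin, and bind all trees to one
    taxon universe (built from the first tree, validated on the rest).

    Parameters
    ----------
    path
        File of Newick trees or a NEXUS trees block (translate tables and
        ``[&U]`` comments honoured).
    format
        ``"newick-list"`` or ``"nexus"``.
    burnin
        Fraction in [0, 1): the first ``floor(burnin * T)`` trees on file
        are discarded.
    label
        Analysis label recorded on the sample and every tree in it.
    """
    if not 0 <= burnin < 1:
        raise ArgumentError(f"burnin must lie in [0, 1), got {burnin}")
    if format not in FORMATS:
        raise ArgumentError(f"unknown format {format!r}; expected one of {FORMATS}")
    schema = "newick" if format == "newick-list" else "nexus"
    try:
        dtrees = dendropy.TreeList.get(path=path, schema=schema,
                                       preserve_underscores=True,
                                       suppress_internal_node_taxa=True)
    except FileNotFoundError:
        raise
    except Exception as exc:
        raise NewickParseError(f"could not parse {path!r}: {exc}") from None
    total = len(dtrees)
    if total == 0:
        raise ValidationError(f"no trees found in {path!r}")
    drop = math.floor(burnin * total + 1e-9)
    kept = dtrees[drop:]
    index: TaxonIndex | None = None
    trees: list[Tree] = []
    for k, dt in enumerate(kept):
        try:
            t = _dendropy_to_tree(dt, index)
        except ValidationError as exc:
            raise ValidationError(
                f"tree {drop + k + 1} of {path!r}: {exc}") from None
        if index is None:
            index = t.index
        trees.append(t)
    return TreeSample(trees=trees, analysis_label=label,
                      burnin_applied=burnin, source_path=str(path))


def pool_samples(samples: list[TreeSample]) -> TreeSample:
    """Concatenate samples into one pooled sample; every tree keeps its
    source analysis label. All samples must share an identical taxon
    universe (same labels, same order)."""
    if not samples:
        raise ArgumentError("nothing to pool: empty sample list")
    index = samples[0].index
    for s in samples[1:]:
        if s.index != index:
            a, b = set(index.labels), set(s.index.labels)
            raise ValidationError(
                "taxon universes differ between samples "
                f"({samples[0].analysis_label!r} vs {s.analysis_label!r}): "
                f"symmetric difference {sorted(a ^ b)}")
    trees: list[Tree] = []
    labels: list[str] = []
    for s in samples:
        trees.extend(s.trees)
        labels.extend(s.tree_labels)
    name = "+".join(dict.fromkeys(s.analysis_label for s in samples))
    return TreeSample(trees=trees, analysis_label=name, tree_labels=labels)


# --------------------------------------------------------------------- #
# writing

_NEEDS_QUOTING = set(" ()[]{}:;,'\"\t\n")


def _fmt_label(label: str) -> str:
    if any(c in _NEEDS_QUOTING for c in label):
        return "'" + label.replace("'", "''") + "'"
    return label


def write_newick(tree: Tree, supports: dict | None = None) -> str:
    """Serialize a tree to a ';'-terminated Newick string.

    The output is deterministic (children ordered by lowest taxon rank in
    their subtree) and round-trips through :func:`parse_newick` to an
    identical topology. If ``supports`` maps splits (canonical masks or
    objects with a ``.mask``) to fractions, they are written as internal
    node labels with two decimals; every key must be a split of ``tree``.
    """
    full = tree.index.full_mask
    present = tree.split_masks()
    norm: dict[int, float] = {}
    if supports:
        for key, val in supports.items():
            mask = canonical_mask(int(getattr(key, "mask", key)), full)
            if mask not in present:
                raise ValidationError(
                    f"support key {tree.index.labels_of(mask)} is not a split of the tree")
            norm[mask] = float(val)

    if tree.n_leaves == 2:
        a, b = (tree.leaf_label[n] for n in sorted(tree.leaf_label))
        return f"({_fmt_label(a)},{_fmt_label(b)});"

    first_leaf = tree.label_node[tree.index.labels[0]]
    root = next(iter(tree.adj[first_leaf]))
    masks = tree.subtree_masks(root)

    def sort_key(node: int) -> int:
        m = masks[node]
        return (m & -m).bit_length()  # lowest taxon rank in subtree

    def render(node: int, parent: int) -> str:
        if node in tree.leaf_label:
            return _fmt_label(tree.leaf_label[node])
        kids = sorted((v for v in tree.adj[node] if v != parent), key=sort_key)
        body = "(" + ",".join(render(v, node) for v in kids) + ")"
        if parent != -1:
            cm = canonical_mask(masks[node], full)
            if cm in norm:
                body += f"{norm[cm]:.2f}"
        return body

    return render(root, -1) + ";"


def write_newick_list(sample: TreeSample, path: str) -> None:
    """Write a sample as one Newick tree per line."""
    with open(path, "w") as fh:
        for t in sample.trees:
            fh.write(write_newick(t) + "\n")
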