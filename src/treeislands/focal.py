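"""Clade-constraint hypotheses about a focal taxon.

The scientific question this module answers is the one a reviewer asks of
a posterior sample for a newly placed fossil: in how many sampled
topologies does the focal terminal form a clade with taxon group X (and
not with Y)? Input trees are unrooted, so clade talk requires a root: a
single declared outgroup leaf roots each tree on its pendant edge, and a
clade is then any split side not containing the outgroup, plus the root
clade of all non-outgroup taxa.

A :class:`Hypothesis` is the generic clade-existence constraint: there is
a clade containing the focal taxon and all of ``require_all``, at least
one of ``require_any`` (if given), and none of ``forbid``. Each tree's
full set of satisfied hypotheses is its category, so overlapping
hypotheses ("with A", "with B", "with both") fall out as distinct
categories, and trees satisfying nothing are counted under "none" —
totals are always conserved.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

from .errors import ValidationError
from .taxa import TaxonIndex
from .tree import Tree
from .tree_io import TreeSample

__all__ = ["Hypothesis", "ClassificationTable", "clades_of", "clade_masks_of",
           "satisfies", "classify_sample", "sister_position_report", "NONE_CATEGORY"]

NONE_CATEGORY: tuple[str, ...] = ()


@dataclass(frozen=True)
class Hypothesis:
    """A clade constraint on a focal taxon.

    ``require_all`` taxa must all be inside the clade, at least one
    ``require_any`` taxon must be inside (vacuous when empty), and no
    ``forbid`` taxon may be inside.
    """

    name: str
    focal: str
    require_all: frozenset[str] = frozenset()
    require_any: frozenset[str] = frozenset()
    forbid: frozenset[str] = frozenset()
    display_color: str | None = None

    def __post_init__(self):
        object.__setattr__(self, "require_all", frozenset(self.require_all))
        object.__setattr__(self, "require_any", frozenset(self.require_any))
        object.__setattr__(self, "forbid", frozenset(self.forbid))
        if not self.name:
            raise ValidationError("hypothesis needs a name")
        if not (self.require_all or self.require_any):
            raise ValidationError(
                f"hypothesis {self.name!r}: at least one of require_all/require_any "
                "must be non-empty")
        if self.focal in self.require_all | self.require_any | self.forbid:
            raise ValidationError(
                f"hypothesis {self.name!r}: focal taxon may not appear in its own constraints")
        if (self.require_all | self.require_any) & self.forbid:
            raise ValidationError(
                f"hypothesis {self.name!r}: require and forbid sets overlap")

    def masks(self, index: TaxonIndex) -> tuple[int, int, int, int]:
        """(focal, require_all, require_any, forbid) as bit-vectors."""
        return (1 << index.position(self.focal),
                index.mask(self.require_all),
                index.mask(self.require_any),
                index.mask(self.forbid))


@dataclass
class ClassificationTable:
    """Per-tree satisfied-hypothesis categories with conserved totals."""

    per_tree: list[tuple[str, str, tuple[str, ...]]]  # (tree id, analysis, category)
    category_counts: dict[tuple[str, ...], int]
    hypothesis_counts: dict[str, int]

    @property
    def total(self) -> int:
        return len(self.per_tree)

    def to_tsvs(self, per_tree_path: str, counts_path: str) -> None:
        with open(per_tree_path, "w") as fh:
            fh.write("tree_id\tanalysis\tcategory\n")
            for tid, ana, cat in self.per_tree:
                fh.write(f"{tid}\t{ana}\t{_cat_name(cat)}\n")
        with open(counts_path, "w") as fh:
            fh.write("category\tcount\n")
            for cat, c in sorted(self.category_counts.items(),
                                 key=lambda kv: (-kv[1], kv[0])):
                fh.write(f"{_cat_name(cat)}\t{c}\n")


def _cat_name(cat: tuple[str, ...]) -> str:
    return "+".join(cat) if cat else "none"


# --------------------------------------------------------------------- #

def clade_masks_of(tree: Tree, outgroup: str) -> frozenset[int]:
    """All clade bit-vectors of ``tree`` rooted on the outgroup's pendant
    edge: for every nontrivial split the side without the outgroup, plus
    the root clade of all non-outgroup taxa."""
    if outgroup not in tree.label_node:
        raise ValidationError(f"outgroup label {outgroup!r} absent from tree")
    out_bit = 1 << tree.index.position(outgroup)
    full = tree.index.full_mask
    clades = {full ^ out_bit}
    for m in tree.split_masks():
        side = m if not m & out_bit else m ^ full
        clades.add(side)
    return frozenset(clades)


def clades_of(tree: Tree, outgroup: str) -> frozenset[frozenset[str]]:
    """Label-set view of :func:`clade_masks_of`."""
    idx = tree.index
    return frozenset(frozenset(idx.labels_of(m)) for m in clade_masks_of(tree, outgroup))


def satisfies(tree: Tree, h: Hypothesis, outgroup: str) -> bool:
    """True iff some clade of the outgroup-rooted tree contains the focal
    taxon and all of ``require_all``, intersects ``require_any`` (if any),
    and avoids ``forbid``."""
    focal_m, all_m, any_m, forbid_m = h.masks(tree.index)
    if focal_m == 1 << tree.index.position(outgroup):
        raise ValidationError("focal taxon cannot be the outgroup")
    for clade in clade_masks_of(tree, outgroup):
        if (clade & focal_m
                and clade & all_m == all_m
                and (not any_m or clade & any_m)
                and not clade & forbid_m):
            return True
    return False


def classify_sample(sample: TreeSample, hypotheses: list[Hypothesis],
                    outgroup: str) -> ClassificationTable:
    """Evaluate every hypothesis on every tree of the sample.

    A tree's category is the sorted tuple of hypothesis names it
    satisfies (``()``, reported as "none", when it satisfies nothing).
    """
    if not hypotheses:
        raise ValidationError("need at least one hypothesis")
    names = [h.name for h in hypotheses]
    if len(set(names)) != len(names):
        raise ValidationError("hypothesis names must be unique")
    index = sample.index
    compiled = [(h.name, h.masks(index)) for h in hypotheses]
    out_bit = 1 << index.position(outgroup)
    per_tree = []
    category_counts: Counter[tuple[str, ...]] = Counter()
    hypothesis_counts: Counter[str] = Counter()
    for i, tree in enumerate(sample.trees):
        clades = clade_masks_of(tree, outgroup)
        satisfied = []
        for name, (focal_m, all_m, any_m, forbid_m) in compiled:
            if focal_m == out_bit:
                raise ValidationError("focal taxon cannot be the outgroup")
            for clade in clades:
                if (clade & focal_m and clade & all_m == all_m
                        and (not any_m or clade & any_m)
                        and not clade & forbid_m):
                    satisfied.append(name)
                    break
        cat = tuple(sorted(satisfied))
        per_tree.append((f"tree_{i}", sample.tree_labels[i], cat))
        category_counts[cat] += 1
        for name in satisfied:
            hypothesis_counts[name] += 1
    return ClassificationTable(per_tree=per_tree,
                               category_counts=dict(category_counts),
                               hypothesis_counts=dict(hypothesis_counts))


def sister_position_report(sample: TreeSample, focal: str,
                           groups: dict[str, set[str]],
                           outgroup: str) -> dict[str, int]:
    """For each named taxon group G, count trees in which the focal taxon
    is the direct sister of exactly G (the tree has a clade equal to
    {focal} | G). Returns counts for every group, zeros included; the TSV
    export relegates zero-count groups to a footer."""
    if not groups:
        raise ValidationError("no groups given")
    index = sample.index
    focal_bit = 1 << index.position(focal)
    targets = {}
    for name, members in groups.items():
        if focal in members:
            raise ValidationError(f"group {name!r} contains the focal taxon")
        targets[name] = index.mask(members) | focal_bit
    counts = dict.fromkeys(groups, 0)
    for tree in sample.trees:
        clades = clade_masks_of(tree, outgroup)
        for name, target in targets.items():
            if target in clades:
                counts[name] += 1
    return counts


def export_sister_positions(counts: dict[str, int], path: str) -> None:
    """TSV of non-zero sister-position counts; zero-count groups are
    listed in a comment footer so the tested set stays on record."""
    nonzero = {k: v for k, v in counts.items() if v}
    zero = [k for k, v in counts.items() if not v]
    with open(path, "w") as fh:
        fh.write("group\ttrees_with_focal_sister\n")
        for k, v in sorted(nonzero.items(), key=lambda kv: (-kv[1], kv[0])):
            fh.write(f"{k}\t{v}\n")
        if zero:
            fh.write("# zero-count groups: " + ", ".join(sorted(zero)) + "\n")
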