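"""Posterior-like tree samples with known island structure.

Real Bayesian/parsimony tree samples for a focal fossil typically fall
into *islands*: clusters of topologies that agree on where the focal
terminal attaches (sister to taxon X, inside group G, ...) and differ by
local rearrangements. This module generates such samples with exact,
verifiable ground truth: each :class:`IslandSpec` fixes a target category
(a set of satisfied placement hypotheses), an attachment region and a
per-tree NNI jitter budget; every generated tree is classified and
rejection-resampled until its satisfied-hypothesis set matches the
island's target, so realized category counts equal the spec *by
construction*, not in expectation.

Within-island jitter uses NNI moves only: a single NNI changes exactly
one bipartition, so the RF radius of an island is directly controlled by
``jitter_moves``. Jitter never touches the stem branch of the attachment
region, keeping the target placement available.
"""

from __future__ import annotations

import random
import warnings
from collections.abc import Iterable, Sequence
from dataclasses import dataclass, field

from .errors import ArgumentError, GenerationError, ValidationError
from .focal import Hypothesis, clade_masks_of
from .taxa import TaxonIndex
from .tree import Tree, canonical_mask
from .tree_io import TreeSample

__all__ = ["IslandSpec", "SyntheticTruth", "random_binary_tree", "nni_move",
           "generate_sample", "random_island_scenario"]

RETRY_BUDGET = 100


@dataclass(frozen=True)
class IslandSpec:
    """One island of trees: a target category, size, attachment region and
    within-island NNI jitter.

    ``target`` is a hypothesis name, an iterable of names (the tree must
    satisfy exactly that set), or ``"none"`` (the tree must satisfy no
    hypothesis). ``attachment_pool`` lists leaves whose surrounding edges
    are candidates for attaching the focal taxon; empty means anywhere
    (only sensible with target ``"none"``).
    """

    name: str
    target: str | tuple[str, ...] = "none"
    size: int = 1
    attachment_pool: frozenset[str] = frozenset()
    jitter_moves: int = 0

    def __post_init__(self):
        object.__setattr__(self, "attachment_pool", frozenset(self.attachment_pool))
        if self.size < 1:
            raise ArgumentError(f"island {self.name!r}: size must be >= 1")
        if self.jitter_moves < 0:
            raise ArgumentError(f"island {self.name!r}: jitter_moves must be >= 0")
        if not self.attachment_pool and self.target_category() != frozenset():
            raise ArgumentError(
                f"island {self.name!r}: attachment_pool may be empty only for target 'none'")

    def target_category(self) -> frozenset[str]:
        t = self.target
        if isinstance(t, str):
            return frozenset() if t == "none" else frozenset([t])
        return frozenset(t)


@dataclass
class SyntheticTruth:
    """Exact generation record: intended category per tree and realized
    island sizes (equal to the spec sizes by construction)."""

    per_tree: list[tuple[int, str, tuple[str, ...]]]  # (tree idx, island, category)
    island_counts: dict[str, int]
    category_counts: dict[tuple[str, ...], int]
    seed: int

    def to_tsv(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write("tree_idx\tisland\tcategory\n")
            for i, isl, cat in self.per_tree:
                fh.write(f"{i}\t{isl}\t{'+'.join(cat) if cat else 'none'}\n")


# --------------------------------------------------------------------- #

def random_binary_tree(labels: Sequence[str], seed: int) -> Tree:
    """Uniform unrooted binary tree by sequential random attachment:
    start from the 3-leaf star and attach each further leaf to an edge
    drawn uniformly at random. Deterministic given ``seed``."""
    labels = [str(l) for l in labels]
    if len(labels) < 4:
        raise ArgumentError("need at least 4 labels for a binary tree")
    index = TaxonIndex(sorted(labels))
    rng = random.Random(seed)
    adj: dict[int, set[int]] = {0: {3}, 1: {3}, 2: {3}, 3: {0, 1, 2}}
    leaf_label = {0: labels[0], 1: labels[1], 2: labels[2]}
    edges: list[tuple[int, int]] = [(0, 3), (1, 3), (2, 3)]
    next_id = 4
    for lab in labels[3:]:
        u, v = edges.pop(rng.randrange(len(edges)))
        w, leaf = next_id, next_id + 1
        next_id += 2
        adj[u].remove(v)
        adj[v].remove(u)
        adj[w] = {u, v, leaf}
        adj[u].add(w)
        adj[v].add(w)
        adj[leaf] = {w}
        leaf_label[leaf] = lab
        edges.extend([(u, w), (v, w), (leaf, w)])
    return Tree(index, adj, leaf_label)


def nni_move(tree: Tree, rng: random.Random | int,
             avoid_split_mask: int | None = None) -> Tree:
    """One nearest-neighbour interchange across a uniformly chosen
    internal edge (optionally never the edge inducing
    ``avoid_split_mask``). Returns a new tree on the same labels whose RF
    count to the input is 0 or 2. A star tree is returned unchanged with
    a warning."""
    if isinstance(rng, int):
        rng = random.Random(rng)
    candidates = tree.internal_edges()
    if avoid_split_mask is not None:
        full = tree.index.full_mask
        avoid = canonical_mask(avoid_split_mask, full)
        root_leaf = next(iter(tree.leaf_label))
        masks = tree.edge_masks_from(root_leaf)
        keyed = {}
        for (p, u), m in masks.items():
            keyed[frozenset((p, u))] = canonical_mask(m, full)
        candidates = [e for e in candidates if keyed[frozenset(e)] != avoid]
    if not candidates:
        warnings.warn("no eligible internal edge; NNI is a no-op", stacklevel=2)
        return tree.copy()
    u, v = candidates[rng.randrange(len(candidates))]
    new = tree.copy()
    b_opts = sorted(new.adj[u] - {v})
    c_opts = sorted(new.adj[v] - {u})
    b = b_opts[rng.randrange(len(b_opts))]
    c = c_opts[rng.randrange(len(c_opts))]
    new.adj[u].remove(b)
    new.adj[b].remove(u)
    new.adj[v].remove(c)
    new.adj[c].remove(v)
    new.adj[u].add(c)
    new.adj[c].add(u)
    new.adj[v].add(b)
    new.adj[b].add(v)
    return new


# --------------------------------------------------------------------- #

def _satisfied_set(tree: Tree, compiled: list[tuple[str, tuple[int, int, int, int]]],
                   outgroup: str) -> frozenset[str]:
    clades = clade_masks_of(tree, outgroup)
    names = []
    for name, (focal_m, all_m, any_m, forbid_m) in compiled:
        for clade in clades:
            if (clade & focal_m and clade & all_m == all_m
                    and (not any_m or clade & any_m)
                    and not clade & forbid_m):
                names.append(name)
                break
    return frozenset(names)


def generate_sample(base_labels: Sequence[str], focal: str, outgroup: str,
                    islands: Iterable[IslandSpec], hypotheses: list[Hypothesis],
                    seed: int, backbone: Tree | None = None,
                    retry_budget: int = RETRY_BUDGET) -> tuple[TreeSample, SyntheticTruth]:
    """Generate a pooled tree sample with exact island structure.

    One backbone tree on ``base_labels`` (random unless given) is jittered
    per tree by restricted NNI moves, the focal taxon is attached on an
    edge inside the island's attachment region, and the result is kept
    only if its satisfied-hypothesis set equals the island's target
    category. Exhausting the retry budget (an unsatisfiable island spec)
    raises :class:`GenerationError` naming the island.
    """
    islands = list(islands)
    if not islands:
        raise ArgumentError("need at least one island spec")
    base_labels = [str(l) for l in base_labels]
    if focal in base_labels:
        raise ValidationError("focal taxon must not appear in base_labels")
    if outgroup not in base_labels:
        raise ValidationError("outgroup must appear in base_labels")
    hyp_names = {h.name for h in hypotheses}
    for isl in islands:
        unknown = isl.target_category() - hyp_names
        if unknown:
            raise ValidationError(f"island {isl.name!r} targets unknown hypotheses {sorted(unknown)}")

    rng = random.Random(seed)
    if backbone is None:
        backbone = random_binary_tree(base_labels, rng.randrange(2 ** 31))
    elif set(backbone.index.labels) != set(base_labels):
        raise ValidationError("backbone leaf set must equal base_labels")

    index_all = TaxonIndex(sorted(base_labels + [focal]))
    compiled = [(h.name, h.masks(index_all)) for h in hypotheses]
    base_index = backbone.index
    out_node = backbone.label_node[outgroup]

    trees: list[Tree] = []
    tree_labels: list[str] = []
    per_tree: list[tuple[int, str, tuple[str, ...]]] = []
    idx = 0
    for isl in islands:
        pool_mask = base_index.mask(isl.attachment_pool)
        target = isl.target_category()
        # minimal backbone clade spanning the pool: its stem branch is
        # protected from jitter so the attachment region stays intact
        poolspan = None
        if pool_mask:
            clades = [c for c in clade_masks_of(backbone, outgroup)
                      if c & pool_mask == pool_mask]
            poolspan = min(clades, key=lambda c: c.bit_count(), default=None)
        for _ in range(isl.size):
            for attempt in range(retry_budget):
                t = backbone.copy()
                for _ in range(isl.jitter_moves):
                    t = nni_move(t, rng, avoid_split_mask=poolspan)
                # candidate edges: away-from-outgroup side within the pool
                emasks = t.edge_masks_from(t.label_node[outgroup])
                if pool_mask:
                    cand = sorted((p, u) for (p, u), m in emasks.items()
                                  if m & pool_mask == m)
                else:
                    cand = sorted(emasks)
                if not cand:
                    continue
                edge = cand[rng.randrange(len(cand))]
                full_tree = Tree(index_all,
                                 {n: set(nb) for n, nb in t.adj.items()},
                                 dict(t.leaf_label), validate=False)
                full_tree.attach_leaf(edge, focal)
                full_tree._validate()
                if _satisfied_set(full_tree, compiled, outgroup) == target:
                    break
            else:
                raise GenerationError(
                    f"island {isl.name!r}: could not realize target category "
                    f"{sorted(target) or ['none']} within {retry_budget} retries")
            trees.append(full_tree)
            tree_labels.append(isl.name)
            per_tree.append((idx, isl.name, tuple(sorted(target))))
            idx += 1

    sample = TreeSample(trees=trees, analysis_label="synthetic",
                        tree_labels=tree_labels)
    from collections import Counter
    truth = SyntheticTruth(
        per_tree=per_tree,
        island_counts={isl.name: isl.size for isl in islands},
        category_counts=dict(Counter(tuple(sorted(isl.target_category()))
                                     for isl in islands for _ in range(isl.size))),
        seed=seed)
    return sample, truth


# --------------------------------------------------------------------- #

@dataclass
class IslandScenario:
    """A randomly drawn but fully specified generation scenario, used for
    exact-recovery testing."""

    base_labels: list[str]
    focal: str
    outgroup: str
    groups: dict[str, set[str]]
    hypotheses: list[Hypothesis]
    islands: list[IslandSpec]
    backbone: Tree
    seed: int

    def generate(self) -> tuple[TreeSample, SyntheticTruth]:
        return generate_sample(self.base_labels, self.focal, self.outgroup,
                               self.islands, self.hypotheses, self.seed,
                               backbone=self.backbone)

    def expected_category_counts(self) -> dict[tuple[str, ...], int]:
        from collections import Counter
        return dict(Counter(tuple(sorted(isl.target_category()))
                            for isl in self.islands for _ in range(isl.size)))


def random_island_scenario(seed: int, n_taxa: tuple[int, int] = (20, 40),
                           n_islands: tuple[int, int] = (3, 5),
                           island_size: tuple[int, int] = (34, 100)) -> IslandScenario:
    """Draw a random scenario: a random binary backbone, disjoint backbone
    clades as hypothesis groups (one mutually exclusive hypothesis each),
    and one island per hypothesis. Recovery is exact by design: every
    clade chosen as a group is protected during jitter, and hypotheses
    forbid each other's members."""
    rng = random.Random(seed)
    n = rng.randint(*n_taxa)
    focal, outgroup = "FOCAL", "OUT_root"
    base = [outgroup] + [f"T{i:02d}" for i in range(1, n - 1)]
    backbone = random_binary_tree(base, rng.randrange(2 ** 31))
    k = rng.randint(*n_islands)
    # disjoint small clades of the outgroup-rooted backbone as groups
    index = backbone.index
    clades = sorted(clade_masks_of(backbone, outgroup),
                    key=lambda m: (m.bit_count(), m))
    chosen: list[int] = []
    small = [m for m in clades if 1 <= m.bit_count() <= 4]
    # include single leaves as degenerate clades
    for lab in index.labels:
        if lab != outgroup:
            small.append(1 << index.position(lab))
    rng.shuffle(small)
    for m in small:
        if all(m & c == 0 for c in chosen):
            chosen.append(m)
        if len(chosen) == k:
            break
    groups = {f"group_{i}": set(index.labels_of(m)) for i, m in enumerate(chosen)}
    hypotheses = []
    for name, members in groups.items():
        others = set().union(*(g for gn, g in groups.items() if gn != name))
        hypotheses.append(Hypothesis(name=f"with_{name}", focal=focal,
                                     require_all=frozenset(members),
                                     forbid=frozenset(others)))
    islands = [IslandSpec(name=f"island_{i}", target=f"with_group_{i}",
                          size=rng.randint(*island_size),
                          attachment_pool=frozenset(groups[f"group_{i}"]),
                          jitter_moves=rng.choice([0, 1, 2]))
               for i in range(len(chosen))]
    return IslandScenario(base_labels=base, focal=focal, outgroup=outgroup,
                          groups=groups, hypotheses=hypotheses, islands=islands,
                          backbone=backbone, seed=rng.randrange(2 ** 31))
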