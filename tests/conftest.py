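"""Shared fixtures and independent oracles.

The oracles here deliberately avoid the package's split machinery: splits
are enumerated by removing each internal edge and flooding the two
components, and clades by rerooting with the same flood fill. They exist
so the fast bit-vector implementations are checked against an
implementation too simple to be wrong.
"""

from __future__ import annotations

import random

import pytest

from treeislands.synthetic import random_binary_tree
from treeislands.tree import Tree


def labels_for(n: int) -> list[str]:
    return [f"L{i:02d}" for i in range(n)]


def random_tree(n: int, seed: int) -> Tree:
    return random_binary_tree(labels_for(n), seed)


def _component(tree: Tree, start: int, banned_edge: frozenset[int]) -> set[int]:
    seen = {start}
    stack = [start]
    while stack:
        u = stack.pop()
        for v in tree.adj[u]:
            if frozenset((u, v)) == banned_edge or v in seen:
                continue
            seen.add(v)
            stack.append(v)
    return seen


def naive_splits(tree: Tree) -> set[frozenset[str]]:
    """Nontrivial splits by edge removal + flood fill, each represented by
    the frozen label set of the side not containing the first taxon."""
    first = tree.index.labels[0]
    out = set()
    for u, v in tree.edges():
        side_u = _component(tree, u, frozenset((u, v)))
        labels_u = frozenset(tree.leaf_label[x] for x in side_u if x in tree.leaf_label)
        labels_v = frozenset(tree.index.labels) - labels_u
        if len(labels_u) < 2 or len(labels_v) < 2:
            continue
        out.add(labels_v if first in labels_u else labels_u)
    return out


def naive_rf(a: Tree, b: Tree, normalized: bool) -> float:
    sa, sb = naive_splits(a), naive_splits(b)
    count = len(sa ^ sb)
    if not normalized:
        return float(count)
    denom = len(sa) + len(sb)
    return count / denom if denom else 0.0


def naive_clades(tree: Tree, outgroup: str) -> set[frozenset[str]]:
    """Clades of the outgroup-rooted tree by flooding away from the
    outgroup leaf across every edge."""
    out_node = tree.label_node[outgroup]
    clades = {frozenset(tree.index.labels) - {outgroup}}
    for u, v in tree.edges():
        side_u = _component(tree, u, frozenset((u, v)))
        far = side_u if out_node not in side_u else _component(tree, v, frozenset((u, v)))
        labels = frozenset(tree.leaf_label[x] for x in far if x in tree.leaf_label)
        if 2 <= len(labels) <= tree.index.n - 2:
            clades.add(labels)
    return clades


@pytest.fixture(scope="session")
def demo():
    """A small demo-preset sample (120 trees) shared across tests."""
    from treeislands import presets
    from treeislands.synthetic import generate_sample

    sample, truth = generate_sample(
        presets.demo_base_labels(), presets.DEMO_FOCAL, presets.DEMO_OUTGROUP,
        presets.demo_islands(120), presets.demo_hypotheses(), seed=11,
        backbone=presets.demo_backbone())
    return sample, truth


@pytest.fixture
def rng():
    return random.Random(20240201)
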