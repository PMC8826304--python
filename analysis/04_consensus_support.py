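"""Majority-rule consensus and bipartition support.

Builds the consensus tree of the pooled sample and of each island
separately, writes them with per-branch support labels, and reports the
support for the focal clade (focal taxon + Opabinia) — the quantity a
node-support-only reading of the analysis would stop at.

Run from the repository root after 01: python analysis/04_consensus_support.py
"""

import importlib.util
import pathlib

from treeislands import majority_rule_consensus, presets, split_frequencies
from treeislands.splits import export_split_frequencies
from treeislands.tree import canonical_mask
from treeislands.tree_io import TreeSample, write_newick

RESULTS = pathlib.Path("results")

_spec = importlib.util.spec_from_file_location(
    "classify_step", pathlib.Path(__file__).parent / "02_classify_placements.py")
_classify_step = importlib.util.module_from_spec(_spec)
_spec.loader.exec_module(_classify_step)


def main() -> None:
    pooled = _classify_step.load_pooled()
    idx = pooled.index
    focal_clade = canonical_mask(idx.mask([presets.DEMO_FOCAL, "Opabinia"]),
                                 idx.full_mask)

    freqs = split_frequencies(pooled)
    export_split_frequencies(freqs, idx, str(RESULTS / "split_frequencies.tsv"))
    support = next((f for bp, f in freqs.items() if bp.mask == focal_clade), 0.0)
    print(f"pooled sample: {len(pooled)} trees, {len(freqs)} distinct splits")
    print(f"support for (focal, Opabinia) clade: {support:.3f}")

    tree, supports = majority_rule_consensus(pooled)
    with open(RESULTS / "consensus_pooled.nwk", "w") as fh:
        fh.write(write_newick(tree, supports) + "\n")
    print(f"pooled majority-rule consensus: {len(supports)} splits "
          f"-> results/consensus_pooled.nwk")

    for label in dict.fromkeys(pooled.tree_labels):
        trees = [t for t, l in zip(pooled.trees, pooled.tree_labels) if l == label]
        sub_tree, sub_sup = majority_rule_consensus(TreeSample(trees, label))
        path = RESULTS / f"consensus_{label}.nwk"
        with open(path, "w") as fh:
            fh.write(write_newick(sub_tree, sub_sup) + "\n")
        print(f"  {label}: {len(sub_sup)} majority splits -> {path}")


if __name__ == "__main__":
    main()
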