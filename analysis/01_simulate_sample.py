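"""Generate the demo tree sample: four placement islands for a focal
fossil terminal, in the emulated study's proportions (3102 : 251 : 28 :
12 scaled to 500 trees), over a 54-taxon universe.

Writes one Newick list per island under results/trees/ plus the exact
generation truth, mirroring how real runs arrive as one tree file per
analysis.

Run from the repository root: python analysis/01_simulate_sample.py
"""

import pathlib

from treeislands import presets
from treeislands.synthetic import generate_sample
from treeislands.tree_io import TreeSample, write_newick_list

SEED = 1
TOTAL = 500
RESULTS = pathlib.Path("results")


def main() -> None:
    out = RESULTS / "trees"
    out.mkdir(parents=True, exist_ok=True)
    sample, truth = generate_sample(
        presets.demo_base_labels(), presets.DEMO_FOCAL, presets.DEMO_OUTGROUP,
        presets.demo_islands(TOTAL), presets.demo_hypotheses(), SEED,
        backbone=presets.demo_backbone())
    truth.to_tsv(str(RESULTS / "truth.tsv"))
    print(f"generated {len(sample)} trees on {sample.index.n} taxa (seed {SEED})")
    for name in dict.fromkeys(sample.tree_labels):
        trees = [t for t, l in zip(sample.trees, sample.tree_labels) if l == name]
        path = out / f"{name}.nwk"
        write_newick_list(TreeSample(trees, name), str(path))
        print(f"  island {name!r}: {len(trees)} trees -> {path}")
    print(f"truth table -> {RESULTS / 'truth.tsv'}")


if __name__ == "__main__":
    main()
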