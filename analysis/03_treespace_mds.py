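"""Embed the pooled sample in treespace.

Computes the pairwise normalized Robinson-Foulds matrix, applies
classical MDS with the Cailliez additive-constant correction, and writes
coordinates, the eigenvalue spectrum and the two standard scatter plots
(coloured by placement category and by source analysis).

Run from the repository root after 01: python analysis/03_treespace_mds.py
"""

import importlib.util
import pathlib

import numpy as np

from treeislands import classical_mds, classify_sample, presets, rf_matrix
from treeislands.focal import _cat_name
from treeislands.plotting import plot_treespace

RESULTS = pathlib.Path("results")

_spec = importlib.util.spec_from_file_location(
    "classify_step", pathlib.Path(__file__).parent / "02_classify_placements.py")
_classify_step = importlib.util.module_from_spec(_spec)
_spec.loader.exec_module(_classify_step)


def main() -> None:
    pooled = _classify_step.load_pooled()
    table = classify_sample(pooled, presets.demo_hypotheses(), presets.DEMO_OUTGROUP)
    categories = [_cat_name(cat) for _, _, cat in table.per_tree]

    dm = rf_matrix(pooled, normalized=True)
    dm.to_csv(str(RESULTS / "rf_matrix.csv"))
    print(f"RF matrix: {dm.n} x {dm.n}, max distance {dm.values.max():.3f}")

    emb = classical_mds(dm, k=2, apply_correction=True)
    emb.to_csv(str(RESULTS / "embedding.csv"), categories=categories)
    with open(RESULTS / "eigenvalues.txt", "w") as fh:
        fh.write(f"correction_constant\t{emb.correction_constant:.10g}\n")
        fh.write(f"k_retained\t{emb.k}\n")
        for i, lam in enumerate(emb.eigenvalues):
            fh.write(f"eigenvalue_{i + 1}\t{lam:.10g}\n")
    pos = emb.eigenvalues[emb.eigenvalues > 0]
    print(f"Cailliez correction constant: {emb.correction_constant:.4f}")
    print(f"axes 1-2 carry {pos[:2].sum() / pos.sum():.1%} of the positive spectrum")

    # island separation: between- vs within-island embedded distance
    d = emb.pairwise_distances()
    labels = pooled.tree_labels
    within, between = [], []
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            (within if labels[i] == labels[j] else between).append(d[i, j])
    print(f"mean embedded distance within islands {np.mean(within):.3f}, "
          f"between islands {np.mean(between):.3f}")

    color_map = {h.name: h.display_color for h in presets.demo_hypotheses()
                 if h.display_color}
    plot_treespace(emb, categories, str(RESULTS / "treespace_by_category.png"),
                   title="Treespace by focal-taxon placement", color_map=color_map)
    plot_treespace(emb, list(labels), str(RESULTS / "treespace_by_analysis.png"),
                   title="Treespace by analysis")
    print("plots -> results/treespace_by_category.png, results/treespace_by_analysis.png")


if __name__ == "__main__":
    main()
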