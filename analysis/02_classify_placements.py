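"""Classify every sampled topology by where the focal taxon attaches.

Reads the per-island tree files written by 01_simulate_sample.py, pools
them, evaluates the three clade-constraint hypotheses on each tree
(rooted on the priapulid outgroup), and counts trees per category and
per tested sister position.

Run from the repository root after 01: python analysis/02_classify_placements.py
"""

import pathlib

from treeislands import classify_sample, presets, sister_position_report
from treeislands.focal import _cat_name, export_sister_positions
from treeislands.tree_io import pool_samples, read_tree_sample

RESULTS = pathlib.Path("results")


def load_pooled():
    samples = [read_tree_sample(str(p), label=p.stem)
               for p in sorted((RESULTS / "trees").glob("*.nwk"))]
    return pool_samples(samples)


def main() -> None:
    pooled = load_pooled()
    print(f"pooled {len(pooled)} trees from "
          f"{len(dict.fromkeys(pooled.tree_labels))} analyses")
    table = classify_sample(pooled, presets.demo_hypotheses(), presets.DEMO_OUTGROUP)
    table.to_tsvs(str(RESULTS / "per_tree.tsv"), str(RESULTS / "counts.tsv"))
    print("category counts (trees per satisfied-hypothesis set):")
    for cat, c in sorted(table.category_counts.items(), key=lambda kv: -kv[1]):
        print(f"  {_cat_name(cat)}: {c}")
    groups = {k: set(v) for k, v in presets.demo_taxa().items()
              if k in ("opabiniid", "hurdiids", "other_radiodonts", "deuteropods")}
    counts = sister_position_report(pooled, presets.DEMO_FOCAL, groups,
                                    presets.DEMO_OUTGROUP)
    export_sister_positions(counts, str(RESULTS / "sister_positions.tsv"))
    print("sister-position counts (zero-count groups omitted):")
    for name, c in sorted(counts.items(), key=lambda kv: -kv[1]):
        if c:
            print(f"  focal sister to {name}: {c}")


if __name__ == "__main__":
    main()
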