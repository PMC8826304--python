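"""Config-driven end-to-end treespace pipeline.

``run`` executes: read each input with its burnin -> pool -> classify
placements and count sister positions -> RF distance matrix -> classical
MDS (Cailliez-corrected) -> majority-rule consensus per analysis ->
write every table, tree and plot. All numeric outputs are persisted as
plain text so each stage is re-derivable and independently invokable.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np

from . import __version__
from .config import RunConfig
from .errors import TreeIslandsError
from .focal import (ClassificationTable, classify_sample, export_sister_positions,
                    sister_position_report, _cat_name)
from .mds import Embedding, classical_mds
from .plotting import plot_treespace
from .splits import (Bipartition, DistanceMatrix, majority_rule_consensus,
                     rf_matrix)
from .tree_io import TreeSample, pool_samples, read_tree_sample, write_newick

__all__ = ["RunReport", "run", "StageError"]


class StageError(TreeIslandsError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunReport:
    """All results of one pipeline run, with the files backing them."""

    pooled: TreeSample
    classification: ClassificationTable
    sister_counts: dict[str, int]
    distance_matrix: DistanceMatrix
    embedding: Embedding
    consensus: dict[str, tuple]               # analysis label -> (Tree, supports)
    categories: list[str]                     # per-tree category names
    output_files: list[str] = field(default_factory=list)


def _per_analysis(sample: TreeSample) -> dict[str, TreeSample]:
    out: dict[str, TreeSample] = {}
    for label in dict.fromkeys(sample.tree_labels):
        trees = [t for t, l in zip(sample.trees, sample.tree_labels) if l == label]
        out[label] = TreeSample(trees=trees, analysis_label=label)
    return out


def run(config: RunConfig, verbose: bool = False) -> RunReport:
    """Execute the full pipeline described by ``config``.

    Deterministic given fixed inputs. On any stage failure the partial
    outputs written so far are removed and a :class:`StageError` naming
    the stage is raised.
    """
    os.makedirs(config.output_dir, exist_ok=True)
    created: list[str] = []

    def out(name: str) -> str:
        p = os.path.join(config.output_dir, name)
        created.append(p)
        return p

    def log(msg: str) -> None:
        if verbose:
            import sys
            print(msg, file=sys.stderr)

    stage = "read"
    try:
        samples = []
        for spec in config.inputs:
            s = read_tree_sample(spec.path, format=spec.format,
                                 burnin=spec.burnin, label=spec.label)
            log(f"read {len(s)} trees from {spec.path} (burnin {spec.burnin})")
            samples.append(s)

        stage = "pool"
        pooled = pool_samples(samples)
        log(f"pooled {len(pooled)} trees from {len(samples)} analyses")

        stage = "classify"
        table = classify_sample(pooled, config.hypotheses, config.outgroup)
        categories = [_cat_name(cat) for _, _, cat in table.per_tree]
        table.to_tsvs(out("per_tree.tsv"), out("counts.tsv"))
        sister = sister_position_report(pooled, config.focal,
                                        config.groups, config.outgroup) \
            if config.groups else {}
        if sister:
            export_sister_positions(sister, out("sister_positions.tsv"))

        stage = "distances"
        dm = rf_matrix(pooled, normalized=config.distance == "rf_proportion")
        dm.to_csv(out("rf_matrix.csv"))

        stage = "mds"
        emb = classical_mds(dm, k=config.mds_k,
                            apply_correction=config.apply_correction)
        emb.to_csv(out("embedding.csv"), categories=categories)
        with open(out("eigenvalues.txt"), "w") as fh:
            fh.write(f"correction_constant\t{emb.correction_constant:.10g}\n")
            fh.write(f"k_retained\t{emb.k}\n")
            for i, lam in enumerate(emb.eigenvalues):
                fh.write(f"eigenvalue_{i + 1}\t{lam:.10g}\n")

        stage = "consensus"
        consensus = {}
        for label, sub in _per_analysis(pooled).items():
            tree, supports = majority_rule_consensus(sub)
            consensus[label] = (tree, supports)
            with open(out(f"consensus_{label}.nwk"), "w") as fh:
                fh.write(write_newick(tree, supports) + "\n")

        stage = "plot"
        if emb.k >= 2:
            color_map = {h.name: h.display_color for h in config.hypotheses
                         if h.display_color}
            plot_treespace(emb, categories, out("treespace_by_category.png"),
                           title="Treespace by focal-taxon placement",
                           color_map=color_map)
            plot_treespace(emb, list(pooled.tree_labels),
                           out("treespace_by_analysis.png"),
                           title="Treespace by analysis")

        stage = "log"
        with open(out("run_log.txt"), "w") as fh:
            fh.write(f"treeislands {__version__}\n")
            fh.write(f"inputs: {[s.path for s in config.inputs]}\n")
            fh.write(f"burnins: {[s.burnin for s in config.inputs]}\n")
            fh.write(f"pooled trees: {len(pooled)}\n")
            fh.write(f"focal: {config.focal}\noutgroup: {config.outgroup}\n")
            fh.write(f"distance: {config.distance}\n")
            fh.write(f"mds_k: {config.mds_k} (retained {emb.k})\n")
            fh.write(f"correction_constant: {emb.correction_constant:.10g}\n")
            fh.write("category counts:\n")
            for cat, c in sorted(table.category_counts.items(),
                                 key=lambda kv: -kv[1]):
                fh.write(f"  {_cat_name(cat)}\t{c}\n")
    except Exception as exc:
        for p in created:
            if os.path.exists(p):
                os.remove(p)
        if isinstance(exc, StageError):
            raise
        raise StageError(stage, exc) from exc

    return RunReport(pooled=pooled, classification=table, sister_counts=sister,
                     distance_matrix=dm, embedding=emb, consensus=consensus,
                     categories=categories, output_files=created)


def load_distance_csv(path: str) -> DistanceMatrix:
    """Read a square distance CSV (tree ids as header row/column) back
    into a :class:`DistanceMatrix`."""
    import pandas as pd
    df = pd.read_csv(path, index_col=0)
    return DistanceMatrix(values=df.values.astype(float),
                          metric_name="rf_proportion"
                          if np.all(df.values <= 1 + 1e-12) else "rf_count",
                          tree_ids=[str(c) for c in df.columns])
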