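"""Bundled presets: the demo taxon universe, placement hypotheses, and
island layout used throughout the docs and the analysis scripts.

The demo emulates the shape of a published treespace study of a focal
Cambrian fossil: a ~54-taxon panarthropod matrix analysed by Bayesian
inference and parsimony, whose pooled tree sample splits into islands by
where the focal terminal attaches (with the opabiniid *Opabinia*, inside
Deuteropoda, or with radiodonts + deuteropods excluding *Opabinia*).
Everything here is synthetic: taxon names other than the handful of real
genera are placeholders, the backbone is invented, and island sizes are
the study's island proportions (3102 : 251 : 28 : 12) scaled down to a
500-tree sample. The preset demonstrates and tests the method; it does
not reconstruct the study's actual posterior.
"""

from __future__ import annotations

from dataclasses import dataclass

from .focal import Hypothesis
from .synthetic import IslandSpec
from .tree import Tree
from .tree_io import parse_newick

__all__ = ["MatrixAssembly", "STUDY_MATRIX_ASSEMBLY", "demo_taxa",
           "demo_backbone", "demo_hypotheses", "demo_islands", "DEMO_FOCAL",
           "DEMO_OUTGROUP"]


@dataclass(frozen=True)
class MatrixAssembly:
    """Bookkeeping of how a morphological character matrix was assembled
    from its sources: characters retained from a published panarthropod
    matrix, characters imported from radiodont-focused datasets, and
    characters newly developed; taxa counted by preservation status."""

    characters_retained: int
    characters_imported: int
    characters_new: int
    fossil_taxa: int
    extant_taxa: int

    def total_characters(self) -> int:
        return self.characters_retained + self.characters_imported + self.characters_new

    def total_taxa(self) -> int:
        return self.fossil_taxa + self.extant_taxa


#: Assembly accounting of the matrix behind the study the demo emulates:
#: 86 characters kept from the source panarthropod matrix, 14 imported
#: from radiodont datasets, 25 newly developed; 43 fossil + 11 extant taxa.
STUDY_MATRIX_ASSEMBLY = MatrixAssembly(
    characters_retained=86, characters_imported=14, characters_new=25,
    fossil_taxa=43, extant_taxa=11)


# --------------------------------------------------------------------- #
# demo taxon universe (synthetic stand-ins except a few anchor genera)

DEMO_FOCAL = "Utaurora"
DEMO_OUTGROUP = "Priapulid_outgroup"

_BASAL = [f"Lobopodian_{i:02d}" for i in range(1, 14)]          # 13
_HURDIIDS = [f"Hurdiid_{i:02d}" for i in range(1, 9)]           # 8
_OTHER_RADIODONTS = [f"Radiodont_{i:02d}" for i in range(1, 11)]  # 10
_DEUTEROPODS = [f"Deuteropod_{i:02d}" for i in range(1, 21)]    # 20


def demo_taxa() -> dict[str, list[str]]:
    """Named taxon groups of the demo universe (53 base taxa + focal = 54)."""
    return {
        "outgroup": [DEMO_OUTGROUP],
        "basal": list(_BASAL),
        "opabiniid": ["Opabinia"],
        "hurdiids": list(_HURDIIDS),
        "other_radiodonts": list(_OTHER_RADIODONTS),
        "radiodonts": list(_HURDIIDS) + list(_OTHER_RADIODONTS),
        "deuteropods": list(_DEUTEROPODS),
    }


def demo_base_labels() -> list[str]:
    g = demo_taxa()
    return g["outgroup"] + g["basal"] + g["opabiniid"] + g["radiodonts"] + g["deuteropods"]


def demo_backbone() -> Tree:
    """Fixed 53-taxon backbone: a basal grade, then *Opabinia* sister to
    (radiodonts, deuteropods), radiodonts and deuteropods each
    monophyletic. Invented topology, chosen so every demo hypothesis is
    realizable by a single focal attachment."""
    def ladder(labels: list[str], inner: str) -> str:
        out = inner
        for lab in reversed(labels):
            out = f"({lab},{out})"
        return out

    def clade(labels: list[str]) -> str:
        out = labels[-1]
        for lab in reversed(labels[:-1]):
            out = f"({lab},{out})"
        return out

    rad = f"({clade(_HURDIIDS)},{clade(_OTHER_RADIODONTS)})"
    core = f"(Opabinia,({rad},{clade(_DEUTEROPODS)}))"
    newick = f"({DEMO_OUTGROUP},{ladder(_BASAL, core)});"
    return parse_newick(newick)


def demo_hypotheses() -> list[Hypothesis]:
    """The four demo placement categories for the focal taxon.

    These encode one consistent reading of "forms a clade with X":
    ``with_opabinia`` forbids both deuteropods and radiodonts inside the
    clade (the strictest reading); ``with_deuteropoda`` forbids
    radiodonts; ``with_radiodonts_deuteropods_excl_opabinia`` requires
    both groups but excludes *Opabinia*. Category boundaries are plain
    configuration — edit the require/forbid sets to encode another
    reading.
    """
    g = demo_taxa()
    rad = frozenset(g["radiodonts"])
    deu = frozenset(g["deuteropods"])
    return [
        Hypothesis(name="with_opabinia", focal=DEMO_FOCAL,
                   require_all=frozenset(["Opabinia"]),
                   forbid=rad | deu, display_color="#e377c2"),
        Hypothesis(name="with_deuteropoda", focal=DEMO_FOCAL,
                   require_all=deu, forbid=rad, display_color="#4b0082"),
        Hypothesis(name="with_radiodonts_deuteropods_excl_opabinia",
                   focal=DEMO_FOCAL, require_all=rad | deu,
                   forbid=frozenset(["Opabinia"]), display_color="#1f77b4"),
    ]


def demo_islands(total: int = 500) -> list[IslandSpec]:
    """Four islands in the emulated study's proportions (3102 : 251 : 28
    : 12 posterior/MPT trees), scaled to ``total`` trees (default 500 ->
    457 / 37 / 4 / 2)."""
    g = demo_taxa()
    raw = {"opabiniid": 3102, "deuteropod": 251, "radiodont": 28, "mp": 12}
    whole = sum(raw.values())
    sizes = {k: max(1, round(v * total / whole)) for k, v in raw.items()}
    sizes["opabiniid"] += total - sum(sizes.values())  # absorb rounding
    return [
        IslandSpec(name="opabiniid", target="with_opabinia",
                   size=sizes["opabiniid"],
                   attachment_pool=frozenset(["Opabinia"]), jitter_moves=2),
        IslandSpec(name="deuteropod",
                   target=("with_deuteropoda",
                           "with_radiodonts_deuteropods_excl_opabinia"),
                   size=sizes["deuteropod"],
                   attachment_pool=frozenset(g["deuteropods"]), jitter_moves=2),
        IslandSpec(name="radiodont",
                   target="with_radiodonts_deuteropods_excl_opabinia",
                   size=sizes["radiodont"],
                   attachment_pool=frozenset(g["radiodonts"]), jitter_moves=1),
        IslandSpec(name="mp", target="with_opabinia", size=sizes["mp"],
                   attachment_pool=frozenset(["Opabinia"]), jitter_moves=1),
    ]
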