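"""Flat key-value run configuration (INI dialect via configparser).

A run config names the input tree files (with per-file burnin), the
focal taxon and outgroup, named taxon groups, and the placement
hypotheses. Group values are whitespace-separated label lists; inside
hypothesis sets a ``@group`` token expands to the group's members.

Example::

    [run]
    focal = Utaurora
    outgroup = Priapulid_outgroup
    distance = rf_proportion
    mds_k = 2
    apply_correction = true
    output_dir = out

    [inputs]
    bi_min = trees/bi_min.t | nexus | 0.25
    mp = trees/mpts.nwk | newick-list | 0

    [groups]
    radiodonts = Hurdiid_01 Hurdiid_02 Radiodont_01

    [hypothesis:with_opabinia]
    require_all = Opabinia
    forbid = @radiodonts
    color = #e377c2
"""

from __future__ import annotations

import configparser
from dataclasses import dataclass, field

from .errors import ArgumentError, ValidationError
from .focal import Hypothesis

__all__ = ["InputSpec", "RunConfig"]

DISTANCES = ("rf_proportion", "rf_count")


@dataclass(frozen=True)
class InputSpec:
    path: str
    format: str = "newick-list"
    burnin: float = 0.0
    label: str = "sample"


@dataclass
class RunConfig:
    """Everything a pipeline run needs, validated at construction."""

    inputs: list[InputSpec]
    focal: str
    outgroup: str
    groups: dict[str, set[str]] = field(default_factory=dict)
    hypotheses: list[Hypothesis] = field(default_factory=list)
    distance: str = "rf_proportion"
    mds_k: int = 2
    apply_correction: bool = True
    output_dir: str = "out"
    seed: int = 0

    def __post_init__(self):
        if self.distance not in DISTANCES:
            raise ArgumentError(f"distance must be one of {DISTANCES}")
        if self.mds_k < 1:
            raise ArgumentError("mds_k must be >= 1")
        if not self.focal or not self.outgroup:
            raise ValidationError("focal and outgroup must be set")

    # ----------------------------------------------------------------- #

    @classmethod
    def from_file(cls, path: str) -> "RunConfig":
        cp = configparser.ConfigParser()
        read = cp.read(path)
        if not read:
            raise FileNotFoundError(path)
        if "run" not in cp:
            raise ValidationError(f"{path}: missing [run] section")
        run = cp["run"]
        groups = {}
        if "groups" in cp:
            for name, val in cp["groups"].items():
                groups[name] = set(val.split())

        def expand(val: str) -> frozenset[str]:
            out: set[str] = set()
            for tok in val.split():
                if tok.startswith("@"):
                    gname = tok[1:]
                    if gname not in groups:
                        raise ValidationError(f"unknown group reference {tok!r}")
                    out |= groups[gname]
                else:
                    out.add(tok)
            return frozenset(out)

        focal = run.get("focal", "")
        hypotheses = []
        for section in cp.sections():
            if not section.startswith("hypothesis:"):
                continue
            name = section.split(":", 1)[1]
            h = cp[section]
            hypotheses.append(Hypothesis(
                name=name, focal=focal,
                require_all=expand(h.get("require_all", "")),
                require_any=expand(h.get("require_any", "")),
                forbid=expand(h.get("forbid", "")),
                display_color=h.get("color") or None))

        inputs = []
        if "inputs" in cp:
            for label, val in cp["inputs"].items():
                parts = [p.strip() for p in val.split("|")]
                if not parts or not parts[0]:
                    raise ValidationError(f"input {label!r}: empty path")
                fmt = parts[1] if len(parts) > 1 and parts[1] else "newick-list"
                burn = float(parts[2]) if len(parts) > 2 and parts[2] else 0.0
                inputs.append(InputSpec(path=parts[0], format=fmt,
                                        burnin=burn, label=label))

        return cls(inputs=inputs,
                   focal=focal,
                   outgroup=run.get("outgroup", ""),
                   groups=groups,
                   hypotheses=hypotheses,
                   distance=run.get("distance", "rf_proportion"),
                   mds_k=run.getint("mds_k", 2),
                   apply_correction=run.getboolean("apply_correction", True),
                   output_dir=run.get("output_dir", "out"),
                   seed=run.getint("seed", 0))
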