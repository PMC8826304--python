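"""The taxon universe shared by every tree in an analysis.

All split/bipartition arithmetic in this package is carried out on Python
integers used as bit-vectors over taxon positions, so the ordered
:class:`TaxonIndex` is the single source of truth for which bit means which
taxon.
"""

from __future__ import annotations

from collections.abc import Iterable, Sequence

from .errors import ArgumentError, ValidationError

__all__ = ["TaxonIndex"]


class TaxonIndex:
    """A fixed, ordered universe of unique taxon labels.

    Parameters
    ----------
    labels
        Taxon names. They are whitespace-trimmed, must be non-empty and
        unique; their order defines bit positions 0..n-1 used by all
        bipartition masks.
    """

    __slots__ = ("labels", "positions")

    def __init__(self, labels: Sequence[str]):
        cleaned = []
        for lab in labels:
            lab = str(lab).strip()
            if not lab:
                raise ValidationError("empty taxon label")
            cleaned.append(lab)
        if len(set(cleaned)) != len(cleaned):
            dupes = sorted({l for l in cleaned if cleaned.count(l) > 1})
            raise ValidationError(f"duplicate taxon labels: {dupes}")
        self.labels: tuple[str, ...] = tuple(cleaned)
        self.positions: dict[str, int] = {l: i for i, l in enumerate(self.labels)}

    @property
    def n(self) -> int:
        return len(self.labels)

    @property
    def full_mask(self) -> int:
        return (1 << self.n) - 1

    def position(self, label: str) -> int:
        try:
            return self.positions[label]
        except KeyError:
            raise ValidationError(f"unknown taxon label: {label!r}") from None

    def mask(self, labels: Iterable[str]) -> int:
        """Bit-vector with the bit of each given label set."""
        m = 0
        for lab in labels:
            m |= 1 << self.position(lab)
        return m

    def labels_of(self, mask: int) -> tuple[str, ...]:
        """Labels whose bits are set in ``mask``, in index order."""
        return tuple(l for i, l in enumerate(self.labels) if mask >> i & 1)

    def require_min_size(self, k: int = 4) -> None:
        if self.n < k:
            raise ArgumentError(f"need at least {k} taxa, have {self.n}")

    def __len__(self) -> int:
        return self.n

    def __eq__(self, other) -> bool:
        return isinstance(other, TaxonIndex) and self.labels == other.labels

    def __hash__(self) -> int:
        return hash(self.labels)

    def __repr__(self) -> str:
        return f"TaxonIndex(n={self.n}, labels={self.labels[:4]}...)" if self.n > 4 else f"TaxonIndex(labels={self.labels})"
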