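"""Classical multidimensional scaling with additive-constant correction.

Classical MDS (principal coordinates analysis) eigendecomposes the
double-centered squared-distance matrix B = -1/2 J (D o D) J, where
J = I - 11^T/n. When D is a tree-to-tree Robinson-Foulds matrix it is
generally not Euclidean-embeddable and B acquires negative eigenvalues;
the Cailliez additive constant is the smallest c >= 0 such that adding c
to every off-diagonal distance makes B positive semi-definite. It is the
largest eigenvalue of the 2n x 2n companion matrix

    [ 0        2*B1 ]        B1 = -1/2 J (D o D) J
    [ -I      -4*B2 ]        B2 = -1/2 J  D      J

Coordinates are eigenvectors scaled by sqrt(eigenvalue) for the top-k
positive eigenvalues, so inter-point Euclidean distances approximate the
(corrected) input distances. The embedding is unique only up to
rotation/reflection; axis signs are fixed deterministically (first
nonzero coordinate of each axis made positive).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ArgumentError
from .splits import DistanceMatrix

__all__ = ["Embedding", "double_center", "correction_constant", "classical_mds"]

_REL_TOL = 1e-8


@dataclass
class Embedding:
    """MDS coordinates plus the full spectrum and applied correction."""

    coordinates: np.ndarray        # n_points x k, axes by descending eigenvalue
    eigenvalues: np.ndarray        # full descending spectrum of B
    correction_constant: float
    k: int
    tree_ids: list[str] | None = None
    analysis_labels: list[str] | None = None

    def pairwise_distances(self) -> np.ndarray:
        diff = self.coordinates[:, None, :] - self.coordinates[None, :, :]
        return np.sqrt((diff ** 2).sum(-1))

    def to_csv(self, path: str, categories: list[str] | None = None) -> None:
        import pandas as pd
        n = self.coordinates.shape[0]
        data = {"tree_id": self.tree_ids or [f"tree_{i}" for i in range(n)],
                "analysis": self.analysis_labels or [""] * n}
        if categories is not None:
            data["category"] = categories
        for j in range(self.k):
            data[f"axis_{j + 1}"] = self.coordinates[:, j]
        pd.DataFrame(data).to_csv(path, index=False)


def _as_array(D) -> np.ndarray:
    if isinstance(D, DistanceMatrix):
        return np.asarray(D.values, dtype=float)
    a = np.asarray(D, dtype=float)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ArgumentError("distance matrix must be square")
    return a


def double_center(D) -> np.ndarray:
    """B = -1/2 J (D o D) J. Rows and columns of B sum to zero."""
    d = _as_array(D)
    n = d.shape[0]
    if n < 2:
        raise ArgumentError("need at least 2 points to center")
    sq = d ** 2
    row = sq.mean(axis=1, keepdims=True)
    col = sq.mean(axis=0, keepdims=True)
    return -0.5 * (sq - row - col + sq.mean())


def _center(m: np.ndarray) -> np.ndarray:
    row = m.mean(axis=1, keepdims=True)
    col = m.mean(axis=0, keepdims=True)
    return -0.5 * (m - row - col + m.mean())


def correction_constant(D) -> float:
    """Smallest additive constant c >= 0 on off-diagonal distances making
    the double-centered matrix positive semi-definite (0 when D is
    already Euclidean-embeddable). Computed via the companion
    eigenproblem, then verified by re-centering the corrected matrix."""
    d = _as_array(D)
    n = d.shape[0]
    b1 = _center(d ** 2)
    lam = np.linalg.eigvalsh(b1)
    scale = max(abs(lam[0]), abs(lam[-1]), 1.0)
    if lam[0] >= -_REL_TOL * scale:
        return 0.0
    b2 = _center(d)
    z = np.zeros((2 * n, 2 * n))
    z[:n, n:] = 2.0 * b1
    z[n:, :n] = -np.eye(n)
    z[n:, n:] = -4.0 * b2
    c = float(np.max(np.real(np.linalg.eigvals(z))))
    c = max(c, 0.0)
    # post-hoc verification of the PSD contract; absorb eigensolver rounding
    # by nudging c upward by amounts far below the minimality tolerance
    eps = 1e-12 * max(c, 1.0)
    for _ in range(64):
        lam_c = np.linalg.eigvalsh(double_center(apply_constant(d, c)))
        scale_c = max(abs(lam_c[0]), abs(lam_c[-1]), 1.0)
        if lam_c[0] >= -_REL_TOL * scale_c:
            return c
        c += eps
        eps *= 2.0
    raise ArgumentError("additive-constant correction failed to produce a PSD matrix")


def apply_constant(D, c: float) -> np.ndarray:
    """Add c to every off-diagonal distance, keeping the diagonal zero."""
    d = _as_array(D).copy()
    off = ~np.eye(d.shape[0], dtype=bool)
    d[off] += c
    return d


def classical_mds(D, k: int = 2, apply_correction: bool = True) -> Embedding:
    """Classical MDS of a distance matrix.

    Parameters
    ----------
    D
        A :class:`DistanceMatrix` or square array.
    k
        Number of axes requested; silently reduced (and recorded on the
        returned :class:`Embedding`) if fewer positive eigenvalues exist.
    apply_correction
        Apply the Cailliez additive constant before embedding.
    """
    if k < 1:
        raise ArgumentError("k must be >= 1")
    d = _as_array(D)
    n = d.shape[0]
    if n < 3:
        raise ArgumentError("need at least 3 points to embed")
    c = correction_constant(d) if apply_correction else 0.0
    dc = apply_constant(d, c) if c else d
    b = double_center(dc)
    lam, vec = np.linalg.eigh(b)
    order = np.argsort(lam)[::-1]
    lam = lam[order]
    vec = vec[:, order]
    tol = _REL_TOL * max(np.abs(lam).max(), 1.0)
    lam_clamped = np.where(np.abs(lam) < tol, 0.0, lam)
    n_pos = int(np.sum(lam_clamped > 0))
    k_eff = min(k, n_pos) if n_pos else 0
    coords = vec[:, :k_eff] * np.sqrt(lam_clamped[:k_eff])
    # deterministic reflection: first coordinate of nonzero magnitude positive
    for j in range(k_eff):
        col = coords[:, j]
        nz = np.nonzero(np.abs(col) > 1e-12)[0]
        if nz.size and col[nz[0]] < 0:
            coords[:, j] = -col
    ids = labels = None
    if isinstance(D, DistanceMatrix):
        ids = list(D.tree_ids)
        labels = list(D.analysis_labels) or None
    return Embedding(coordinates=coords, eigenvalues=lam_clamped,
                     correction_constant=c, k=k_eff,
                     tree_ids=ids, analysis_labels=labels)
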