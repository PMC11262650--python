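"""Pairwise dissimilarities, double-centering, and principal coordinates.

Classical multidimensional scaling (principal coordinates analysis, PCoA)
recovers a Euclidean configuration from a dissimilarity matrix D by
eigendecomposition of the doubly-centered matrix

    G = J A J,   A = (-d_ij^2 / 2),   J = I - (1/n) 11^T,

so that for Euclidean distances computed from column-centered data Y one has
G = Y Y^T exactly.  Coordinates are Z = U Lambda^{1/2} for the positive part
of the spectrum.  Non-Euclidean dissimilarities (negative eigenvalues of G)
can be repaired by adding a constant to every off-diagonal dissimilarity
(Cailliez) or to every squared dissimilarity (Lingoes).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist, squareform

__all__ = [
    "DissimilarityMatrix",
    "GramMatrix",
    "CoordinateSet",
    "pairwise_distances",
    "double_center",
    "principal_coordinates",
    "euclidify",
]

_SYM_TOL = 1e-8


def _default_ids(n: int) -> list[str]:
    return [f"s{i}" for i in range(n)]


@dataclass
class DissimilarityMatrix:
    """Symmetric non-negative pairwise dissimilarities with zero diagonal."""

    values: np.ndarray
    metric_name: str = "euclidean"
    sample_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        v = self.values
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError(f"dissimilarity matrix must be square, got shape {v.shape}")
        if not np.isfinite(v).all():
            raise ValueError("dissimilarity matrix contains non-finite values")
        if np.abs(v - v.T).max() > _SYM_TOL * max(1.0, np.abs(v).max()):
            raise ValueError("dissimilarity matrix is not symmetric")
        self.values = (v + v.T) / 2.0
        if np.abs(np.diag(self.values)).max() > _SYM_TOL:
            raise ValueError("dissimilarity matrix must have a zero diagonal")
        np.fill_diagonal(self.values, 0.0)
        if self.values.min() < -_SYM_TOL:
            raise ValueError("dissimilarities must be non-negative")
        self.values[self.values < 0] = 0.0
        if self.sample_ids is None:
            self.sample_ids = _default_ids(self.n)
        elif len(self.sample_ids) != self.n:
            raise ValueError("sample_ids length does not match matrix size")

    @property
    def n(self) -> int:
        return self.values.shape[0]


@dataclass
class GramMatrix:
    """Doubly-centered (squared-dissimilarity scale) inner-product matrix."""

    values: np.ndarray
    is_adjusted: bool = False
    sample_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        v = self.values
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("Gram matrix must be square")
        scale = max(1.0, np.abs(v).max())
        if np.abs(v - v.T).max() > _SYM_TOL * scale:
            raise ValueError("Gram matrix is not symmetric")
        self.values = (v + v.T) / 2.0
        if np.abs(self.values.sum(axis=1)).max() > 1e-6 * scale * self.n:
            raise ValueError("Gram matrix rows do not sum to zero (not doubly centered)")
        if self.sample_ids is None:
            self.sample_ids = _default_ids(self.n)

    @property
    def n(self) -> int:
        return self.values.shape[0]


@dataclass
class CoordinateSet:
    """Principal coordinates Z = U Lambda^{1/2} with their eigenvalues.

    Column j of ``coords`` has squared norm ``eigenvalues[j]``; eigenvalues are
    strictly positive and sorted in non-increasing order.
    ``n_dropped_nonpositive`` counts the spectrum that was discarded.
    """

    coords: np.ndarray
    eigenvalues: np.ndarray
    n_dropped_nonpositive: int = 0
    sample_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.eigenvalues = np.asarray(self.eigenvalues, dtype=float)
        if self.coords.shape[1] != self.eigenvalues.shape[0]:
            raise ValueError("coords / eigenvalues dimension mismatch")
        if self.eigenvalues.size and (
            np.any(self.eigenvalues <= 0) or np.any(np.diff(self.eigenvalues) > 1e-12)
        ):
            raise ValueError("eigenvalues must be positive and non-increasing")
        if self.sample_ids is None:
            self.sample_ids = _default_ids(self.n)

    @property
    def n(self) -> int:
        return self.coords.shape[0]

    @property
    def k(self) -> int:
        return self.coords.shape[1]


def pairwise_distances(
    data: np.ndarray,
    metric: str = "euclidean",
    sample_ids: list[str] | None = None,
) -> DissimilarityMatrix:
    """Compute the pairwise dissimilarity matrix of a samples x features array.

    Parameters
    ----------
    data : array of shape (n, m)
        One row per sample.  Must contain at least two rows and only finite
        values.
    metric : str
        Any symmetric non-negative metric accepted by
        :func:`scipy.spatial.distance.pdist`; Euclidean is the default used
        throughout the downstream adjustment pipeline.
    """
    data = np.atleast_2d(np.asarray(data, dtype=float))
    if data.shape[0] < 2:
        raise ValueError("need at least 2 samples to compute pairwise distances")
    bad = ~np.isfinite(data).all(axis=1)
    if bad.any():
        rows = np.flatnonzero(bad).tolist()
        raise ValueError(f"non-finite feature values in rows {rows}")
    d = squareform(pdist(data, metric=metric))
    return DissimilarityMatrix(d, metric_name=metric, sample_ids=sample_ids)


def centering_matrix(n: int) -> np.ndarray:
    """Gower centering matrix J = I - (1/n) 11^T."""
    return np.eye(n) - np.full((n, n), 1.0 / n)


def double_center(D: DissimilarityMatrix) -> GramMatrix:
    """Double-center -D^2/2 into the Gram matrix G = J A J.

    For Euclidean D computed from data Y, G equals the inner-product matrix
    of the column-centered Y.
    """
    a = -0.5 * D.values**2
    # J A J expanded: subtract row/column means, add grand mean.
    row = a.mean(axis=1, keepdims=True)
    col = a.mean(axis=0, keepdims=True)
    g = a - row - col + a.mean()
    g = (g + g.T) / 2.0
    return GramMatrix(g, sample_ids=list(D.sample_ids))


def _fix_signs(vecs: np.ndarray) -> np.ndarray:
    # reproducible sign: largest-magnitude entry of each column made positive
    idx = np.abs(vecs).argmax(axis=0)
    signs = np.sign(vecs[idx, np.arange(vecs.shape[1])])
    signs[signs == 0] = 1.0
    return vecs * signs


def principal_coordinates(G: GramMatrix, k: int | None = None) -> CoordinateSet:
    """Eigendecompose G and return coordinates Z = U Lambda^{1/2}.

    Eigenvalues at or below ``max(n,1) * eps * lambda_max`` are treated as
    non-positive, dropped and counted.  If nothing survives (constant data), an
    empty coordinate set is returned with a warning.
    """
    vals, vecs = np.linalg.eigh(G.values)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    n = G.n
    lam_max = vals[0] if vals.size else 0.0
    tol = max(n, 1) * np.finfo(float).eps * max(lam_max, 0.0)
    keep = vals > tol
    n_dropped = int((~keep).sum())
    if not keep.any():
        warnings.warn("all eigenvalues non-positive; returning empty coordinate set")
        return CoordinateSet(
            np.empty((n, 0)), np.empty(0), n_dropped_nonpositive=n_dropped,
            sample_ids=list(G.sample_ids),
        )
    vals, vecs = vals[keep], vecs[:, keep]
    if k is not None:
        vals, vecs = vals[:k], vecs[:, :k]
    coords = _fix_signs(vecs) * np.sqrt(vals)
    return CoordinateSet(
        coords, vals, n_dropped_nonpositive=n_dropped, sample_ids=list(G.sample_ids)
    )


def _min_gram_eigenvalue(D: DissimilarityMatrix) -> tuple[float, float]:
    g = double_center(D).values
    vals = np.linalg.eigvalsh(g)
    return float(vals.min()), float(vals.max())


def euclidify(
    D: DissimilarityMatrix, method: str = "cailliez", tol: float = 1e-10
) -> DissimilarityMatrix:
    """Correct a non-Euclidean dissimilarity matrix by an additive constant.

    ``cailliez`` (default) finds the smallest constant c such that
    d_ij + c (i != j) is Euclidean, via the eigenvalues of a 2n x 2n companion
    matrix.  ``lingoes`` adds a constant to the squared dissimilarities:
    d'_ij = sqrt(d_ij^2 + 2c) with c = -lambda_min(G).  Euclidean input is
    returned unchanged (constant 0).  The constant applied is stored in the
    ``correction_constant`` attribute of the result.
    """
    n = D.n
    lam_min, lam_max = _min_gram_eigenvalue(D)
    if lam_min >= -max(tol, 1e-12 * max(lam_max, 1.0)):
        D.correction_constant = 0.0  # type: ignore[attr-defined]
        return D
    if method == "lingoes":
        c = -lam_min
        d2 = D.values**2 + 2.0 * c
        np.fill_diagonal(d2, 0.0)
        out = DissimilarityMatrix(
            np.sqrt(d2), metric_name=f"{D.metric_name}+lingoes",
            sample_ids=list(D.sample_ids),
        )
    elif method == "cailliez":
        J = centering_matrix(n)
        g2 = J @ (-0.5 * D.values**2) @ J
        g1 = J @ (-0.5 * D.values) @ J
        companion = np.block(
            [[np.zeros((n, n)), 2.0 * g2], [-np.eye(n), -4.0 * g1]]
        )
        ev = np.linalg.eigvals(companion)
        c = float(np.max(ev.real))
        d = D.values + c
        np.fill_diagonal(d, 0.0)
        out = DissimilarityMatrix(
            d, metric_name=f"{D.metric_name}+cailliez", sample_ids=list(D.sample_ids)
        )
    else:
        raise ValueError(f"unknown correction method: {method!r}")
    out.correction_constant = c  # type: ignore[attr-defined]
    return out
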