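"""Covariate adjustment of principal coordinates (adjusted PCoA).

Nuisance covariates are assembled into a design matrix X (intercept +
one-hot-coded categoricals with the first level dropped + mean-centered
continuous columns).  The hat matrix H = X (X^T X)^{-1} X^T projects onto the
column space of X; residualizing principal coordinates,

    E = (I - H) Z,

removes any linear association between the coordinates and the covariates.
The adjusted Gram matrix Delta = E E^T = (I - H) G (I - H) carries the same
information and converts back to genuine pairwise distances via
d_ij = sqrt(Delta_ii + Delta_jj - 2 Delta_ij), which equals the Euclidean
distance between rows of E.  Any distance-based embedding method can then be
run on E (Euclidean path) or on the adjusted distances (general path).

The intercept column is mathematically inert for residualizing principal
coordinates (they are exactly column-centered because G is doubly centered)
but is kept so that H is the textbook hat matrix and continuous covariates
are projected as in ordinary least squares.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geometry import CoordinateSet, DissimilarityMatrix, GramMatrix

__all__ = [
    "DesignMatrix",
    "ProjectionMatrix",
    "AdjustedCoordinates",
    "build_design",
    "hat_matrix",
    "adjust_coordinates",
    "adjusted_gram",
    "adjusted_distances",
]


@dataclass
class DesignMatrix:
    """Full-column-rank nuisance design matrix with its encoding metadata."""

    values: np.ndarray
    column_names: list[str]
    encoding_map: dict[str, dict[str, str]] = field(default_factory=dict)
    covariate_names: list[str] = field(default_factory=list)
    sample_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("design matrix must be 2-D")
        if len(self.column_names) != self.values.shape[1]:
            raise ValueError("column_names length mismatch")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def p(self) -> int:
        return self.values.shape[1]


@dataclass
class ProjectionMatrix:
    """Symmetric idempotent projection onto the design column space."""

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        v = self.values
        scale = max(1.0, np.abs(v).max())
        if np.abs(v - v.T).max() > 1e-8 * scale:
            raise ValueError("projection matrix is not symmetric")
        if np.abs(v @ v - v).max() > 1e-8 * scale:
            raise ValueError("projection matrix is not idempotent")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def rank(self) -> int:
        return int(round(np.trace(self.values)))


@dataclass
class AdjustedCoordinates:
    """Residualized coordinates E = (I - H) Z."""

    coords: np.ndarray
    source_eigenvalues: np.ndarray
    adjusted_for: list[str] = field(default_factory=list)
    sample_ids: list[str] | None = None

    @property
    def n(self) -> int:
        return self.coords.shape[0]

    @property
    def k(self) -> int:
        return self.coords.shape[1]


def build_design(
    metadata: pd.DataFrame,
    covariates: list[str],
    covariate_types: dict[str, str] | None = None,
) -> DesignMatrix:
    """Assemble the nuisance design matrix from a per-sample metadata table.

    Categorical covariates are one-hot encoded dropping the lexicographically
    first level; continuous covariates are passed through mean-centered.  An
    intercept column is always included.  Covariate types are inferred from
    the dtype unless overridden via ``covariate_types`` (values ``"categorical"``
    or ``"continuous"``).

    Raises
    ------
    ValueError
        On missing covariates, missing values (offending samples named),
        single-level categoricals, or rank-deficient (collinear) designs with
        the offending pair named.
    """
    covariate_types = covariate_types or {}
    n = len(metadata)
    ids = [str(s) for s in metadata.index]
    cols: list[np.ndarray] = [np.ones(n)]
    names: list[str] = ["intercept"]
    encoding: dict[str, dict[str, str]] = {}
    owner: list[str] = ["intercept"]

    for cov in covariates:
        if cov not in metadata.columns:
            raise ValueError(f"covariate {cov!r} not found in metadata")
        series = metadata[cov]
        if series.isna().any():
            missing = [ids[i] for i in np.flatnonzero(series.isna().to_numpy())]
            raise ValueError(f"covariate {cov!r} has missing values for samples {missing}")
        ctype = covariate_types.get(cov)
        if ctype is None:
            ctype = "continuous" if pd.api.types.is_numeric_dtype(series) else "categorical"
        if ctype == "continuous":
            x = series.to_numpy(dtype=float)
            cols.append(x - x.mean())
            names.append(cov)
            owner.append(cov)
        elif ctype == "categorical":
            levels = sorted(series.astype(str).unique())
            if len(levels) < 2:
                raise ValueError(
                    f"categorical covariate {cov!r} has a single level; zero information"
                )
            cmap = {}
            for lev in levels[1:]:
                col_name = f"{cov}[{lev}]"
                cols.append((series.astype(str) == lev).to_numpy(dtype=float))
                names.append(col_name)
                owner.append(cov)
                cmap[lev] = col_name
            cmap[levels[0]] = "<reference>"
            encoding[cov] = cmap
        else:
            raise ValueError(f"unknown covariate type {ctype!r} for {cov!r}")

    X = np.column_stack(cols)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        pair = _find_collinear_pair(X, names)
        raise ValueError(
            f"design matrix is rank deficient (rank {rank} < {X.shape[1]} columns); "
            f"collinear columns: {pair[0]!r} and {pair[1]!r}"
        )
    return DesignMatrix(
        X, column_names=names, encoding_map=encoding,
        covariate_names=list(covariates), sample_ids=ids,
    )


def _find_collinear_pair(X: np.ndarray, names: list[str]) -> tuple[str, str]:
    # name the first column that lies in the span of the preceding ones, paired
    # with the preceding column it correlates with most
    for j in range(1, X.shape[1]):
        sub = X[:, : j + 1]
        if np.linalg.matrix_rank(sub) < j + 1:
            prev = X[:, :j]
            coef, *_ = np.linalg.lstsq(prev, X[:, j], rcond=None)
            i = int(np.abs(coef).argmax())
            return names[i], names[j]
    return names[0], names[-1]


def hat_matrix(X: DesignMatrix) -> ProjectionMatrix:
    """Projection matrix H = X (X^T X)^{-1} X^T onto the design column space."""
    M = X.values
    if np.linalg.matrix_rank(M) < M.shape[1]:
        raise ValueError("design matrix is rank deficient; cannot form hat matrix")
    # QR route: numerically stable, avoids forming (X^T X)^{-1}
    q, _ = np.linalg.qr(M)
    h = q @ q.T
    return ProjectionMatrix((h + h.T) / 2.0)


def adjust_coordinates(
    Z: CoordinateSet, H: ProjectionMatrix, adjusted_for: list[str] | None = None
) -> AdjustedCoordinates:
    """Residualize principal coordinates: E = (I - H) Z."""
    if Z.n != H.n:
        raise ValueError(f"shape mismatch: Z has {Z.n} samples, H has {H.n}")
    E = Z.coords - H.values @ Z.coords
    return AdjustedCoordinates(
        E, source_eigenvalues=Z.eigenvalues.copy(),
        adjusted_for=list(adjusted_for or []), sample_ids=list(Z.sample_ids),
    )


def adjusted_gram(G: GramMatrix, H: ProjectionMatrix) -> GramMatrix:
    """Covariate-adjusted Gram matrix Delta = (I - H) G (I - H) = E E^T."""
    if G.n != H.n:
        raise ValueError(f"shape mismatch: G has {G.n} samples, H has {H.n}")
    R = np.eye(G.n) - H.values
    delta = R @ G.values @ R
    return GramMatrix((delta + delta.T) / 2.0, is_adjusted=True,
                      sample_ids=list(G.sample_ids))


def adjusted_distances(delta: GramMatrix, tol: float = 1e-8) -> DissimilarityMatrix:
    """Convert an (adjusted) Gram matrix to pairwise distances.

    d_ij = sqrt(Delta_ii + Delta_jj - 2 Delta_ij), the Euclidean distances
    among the rows of any E with Delta = E E^T.  Values that are negative
    under the square root beyond ``tol`` trigger a warning; all negatives are
    clamped to zero.
    """
    diag = np.diag(delta.values)
    d2 = diag[:, None] + diag[None, :] - 2.0 * delta.values
    scale = max(1.0, np.abs(delta.values).max())
    if d2.min() < -tol * scale:
        warnings.warn(
            f"adjusted Gram matrix is not PSD within tolerance "
            f"(min squared distance {d2.min():.3e}); clamping to 0"
        )
    np.clip(d2, 0.0, None, out=d2)
    np.fill_diagonal(d2, 0.0)
    return DissimilarityMatrix(
        np.sqrt(d2), metric_name="adjusted", sample_ids=list(delta.sample_ids)
    )
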