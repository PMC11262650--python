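"""Partial embeddings: confounder-adjusted t-SNE / UMAP and pluggable backends.

The partial-embedding recipe for any distance-based dimension reduction
method is:

1. obtain principal coordinates Z of the input dissimilarities;
2. residualize Z against the nuisance design, E = (I - H) Z;
3. hand E (Euclidean path) or the adjusted distance matrix derived from
   Delta = E E^T (general path) to the embedding method.

Because ||e_i - e_j|| are exactly the adjusted dissimilarities, both routes
feed the embedder identical geometry; only the adjustment is this module's
contribution, embedder optimization is delegated to scikit-learn (t-SNE) and
umap-learn (UMAP).  This module also provides exact, desk-scale constructors
for the two affinity kernels involved: the perplexity-calibrated Gaussian
conditionals of t-SNE and the locally adaptive exponential kernel of UMAP.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .adjustment import (
    AdjustedCoordinates,
    DesignMatrix,
    adjust_coordinates,
    adjusted_distances,
    adjusted_gram,
    hat_matrix,
)
from .geometry import (
    DissimilarityMatrix,
    double_center,
    pairwise_distances,
    principal_coordinates,
)

__all__ = [
    "EmbeddingSpec",
    "EmbeddingResult",
    "AffinityMatrix",
    "tsne_affinities",
    "umap_affinities",
    "adjusted_umap_affinities",
    "pare_input",
    "pare_embed",
    "register_embedder",
    "available_embedders",
]


@dataclass(frozen=True)
class EmbeddingSpec:
    """Parameters of an embedding run.

    ``perplexity`` (t-SNE) and ``n_neighbors`` (UMAP) default to 10 and 15,
    the values used for all downstream evaluation; ``n_coords`` optionally
    caps how many (adjusted) principal coordinates are fed to the embedder.
    """

    method: str = "umap"
    perplexity: float = 10.0
    n_neighbors: int = 15
    output_dim: int = 2
    seed: int = 0
    n_coords: int | None = None
    truncate_before_adjust: bool = False

    def validate(self, n: int) -> None:
        if self.method == "tsne" and not (1 < self.perplexity < n):
            raise ValueError(f"perplexity must be in (1, n={n}), got {self.perplexity}")
        if self.method == "umap" and not (1 <= self.n_neighbors < n):
            raise ValueError(f"n_neighbors must be in [1, n={n}), got {self.n_neighbors}")
        if self.output_dim < 1:
            raise ValueError("output_dim must be >= 1")


@dataclass
class EmbeddingResult:
    """Low-dimensional coordinates plus the provenance needed to rerun them."""

    coords: np.ndarray
    spec: EmbeddingSpec
    adjusted_for: list[str] = field(default_factory=list)
    sample_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if not np.isfinite(self.coords).all():
            raise ValueError("embedding contains non-finite coordinates")


@dataclass
class AffinityMatrix:
    """Symmetric pairwise affinities with the per-sample bandwidths used."""

    values: np.ndarray
    kind: str  # "tsne_p" | "umap_v"
    bandwidths: np.ndarray  # sigma_i for t-SNE; columns (rho_i, tau_i) for UMAP

    @property
    def n(self) -> int:
        return self.values.shape[0]


# ---------------------------------------------------------------------------
# affinity kernels


def _entropy_bits(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum())


def _tsne_row(d2: np.ndarray, target_bits: float, max_iter: int = 400,
              tol: float = 1e-11) -> tuple[np.ndarray, float]:
    """Bisection on beta = 1/(2 sigma^2) so the conditional has the target entropy."""
    d2 = d2 - d2.min()  # shift for numerical stability; conditionals unchanged
    beta_lo, beta_hi = 0.0, np.inf
    beta = 1.0
    for _ in range(max_iter):
        w = np.exp(-beta * d2)
        s = w.sum()
        p = w / s
        h = _entropy_bits(p)
        if abs(h - target_bits) < tol:
            break
        if h > target_bits:  # too flat -> increase beta
            beta_lo = beta
            beta = beta * 2.0 if np.isinf(beta_hi) else (beta + beta_hi) / 2.0
        else:
            beta_hi = beta
            beta = beta / 2.0 if beta_lo == 0.0 else (beta + beta_lo) / 2.0
    return p, beta


def tsne_affinities(D: DissimilarityMatrix, perplexity: float = 10.0) -> AffinityMatrix:
    """Perplexity-calibrated symmetric t-SNE affinities p_ij.

    Each conditional distribution p_{j|i} uses a Gaussian kernel whose
    bandwidth sigma_i is found by bisection so that the conditional entropy is
    log2(perplexity); the symmetrized matrix p_ij = (p_{j|i} + p_{i|j}) / 2n
    sums to one.
    """
    n = D.n
    if not (1 < perplexity < n):
        raise ValueError(f"perplexity must be in (1, n={n}), got {perplexity}")
    d2 = D.values**2
    target = np.log2(perplexity)
    cond = np.zeros((n, n))
    sigmas = np.zeros(n)
    for i in range(n):
        mask = np.arange(n) != i
        row = d2[i, mask]
        if np.all(row == row[0]):
            # all neighbors equidistant: entropy is pinned at log2(n-1)
            if abs(target - np.log2(n - 1)) > 1e-6:
                raise ValueError(
                    f"perplexity {perplexity} infeasible for sample "
                    f"{D.sample_ids[i]!r}: all neighbors equidistant"
                )
            p = np.full(n - 1, 1.0 / (n - 1))
            beta = 1.0
        else:
            p, beta = _tsne_row(row, target)
        cond[i, mask] = p
        sigmas[i] = np.sqrt(1.0 / (2.0 * beta)) if beta > 0 else np.inf
    P = (cond + cond.T) / (2.0 * n)
    np.fill_diagonal(P, 0.0)
    return AffinityMatrix(P, kind="tsne_p", bandwidths=sigmas)


def _smooth_knn_tau(d_nbrs: np.ndarray, rho: float, target: float,
                    max_iter: int = 200, tol: float = 1e-7) -> float:
    """Bisection on tau so sum_j exp(-(d_j - rho)/tau) over neighbors == target."""
    lo, hi = 0.0, np.inf
    tau = 1.0
    for _ in range(max_iter):
        s = np.exp(-(d_nbrs - rho) / tau).sum()
        if abs(s - target) < tol:
            break
        if s > target:
            hi = tau
            tau = tau / 2.0 if lo == 0.0 else (lo + tau) / 2.0
        else:
            lo = tau
            tau = tau * 2.0 if np.isinf(hi) else (tau + hi) / 2.0
        if tau < 1e-12:
            tau = 1e-12
            break
    return tau


def umap_affinities(D: DissimilarityMatrix, n_neighbors: int = 15) -> AffinityMatrix:
    """UMAP fuzzy-set affinities from a dissimilarity matrix.

    Directed memberships v_{j|i} = exp[-(d_ij - rho_i)/tau_i] are nonzero only
    for the ``n_neighbors`` nearest neighbors of i (ties broken by index
    order); rho_i is the distance to the nearest neighbor, so that neighbor's
    membership is exactly 1, and tau_i is calibrated by bisection so the
    membership sum over the neighbor set equals log2(n_neighbors).  The
    symmetric affinity is the fuzzy union v_ij = v_{j|i} + v_{i|j} -
    v_{j|i} v_{i|j}.
    """
    n = D.n
    if not (1 <= n_neighbors < n):
        raise ValueError(f"n_neighbors must be in [1, n={n}), got {n_neighbors}")
    d = D.values
    directed = np.zeros((n, n))
    bands = np.zeros((n, 2))
    for i in range(n):
        order = np.argsort(np.where(np.arange(n) == i, np.inf, d[i]), kind="stable")
        nbrs = order[:n_neighbors]
        d_nbrs = d[i, nbrs]
        rho = d_nbrs[0]
        if n_neighbors == 1:
            tau = 1.0
        else:
            tau = _smooth_knn_tau(d_nbrs, rho, np.log2(n_neighbors))
        directed[i, nbrs] = np.exp(-(d_nbrs - rho) / tau)
        bands[i] = (rho, tau)
    V = directed + directed.T - directed * directed.T
    np.fill_diagonal(V, 0.0)
    return AffinityMatrix(V, kind="umap_v", bandwidths=bands)


def adjusted_umap_affinities(delta, n_neighbors: int = 15,
                             mode: str = "distance") -> AffinityMatrix:
    """UMAP affinities from an adjusted Gram matrix Delta = E E^T.

    ``mode="distance"`` (canonical) first converts Delta to the genuine
    pairwise distances among rows of E and applies the standard kernel.
    ``mode="gram"`` plugs the raw Gram entries delta_ij into the exponential
    kernel directly; Gram entries are inner products, not dissimilarities
    (they can be negative, with a nonzero diagonal), so this variant is kept
    only as an explicitly requested literal alternative.
    """
    if mode == "distance":
        return umap_affinities(adjusted_distances(delta), n_neighbors)
    if mode != "gram":
        raise ValueError(f"mode must be 'distance' or 'gram', got {mode!r}")
    n = delta.n
    if not (1 <= n_neighbors < n):
        raise ValueError(f"n_neighbors must be in [1, n={n}), got {n_neighbors}")
    g = delta.values
    directed = np.zeros((n, n))
    bands = np.zeros((n, 2))
    for i in range(n):
        order = np.argsort(np.where(np.arange(n) == i, np.inf, g[i]), kind="stable")
        nbrs = order[:n_neighbors]  # smallest delta_ij = "nearest" in this reading
        g_nbrs = g[i, nbrs]
        rho = g_nbrs[0]
        tau = 1.0 if n_neighbors == 1 else _smooth_knn_tau(g_nbrs, rho,
                                                           np.log2(n_neighbors))
        directed[i, nbrs] = np.exp(-(g_nbrs - rho) / tau)
        bands[i] = (rho, tau)
    V = directed + directed.T - directed * directed.T
    np.fill_diagonal(V, 0.0)
    return AffinityMatrix(V, kind="umap_v", bandwidths=bands)


# ---------------------------------------------------------------------------
# embedder registry


def _run_tsne(x: np.ndarray, is_distance: bool, spec: EmbeddingSpec) -> np.ndarray:
    from sklearn.manifold import TSNE

    tsne = TSNE(
        n_components=spec.output_dim,
        perplexity=spec.perplexity,
        metric="precomputed" if is_distance else "euclidean",
        init="random",
        random_state=spec.seed,
        n_jobs=1,
    )
    return np.asarray(tsne.fit_transform(x), dtype=float)


def _run_umap(x: np.ndarray, is_distance: bool, spec: EmbeddingSpec) -> np.ndarray:
    import warnings

    import umap

    with warnings.catch_warnings():
        # umap-learn warns that a fixed random_state disables parallelism;
        # determinism is the point here
        warnings.simplefilter("ignore")
        reducer = umap.UMAP(
            n_components=spec.output_dim,
            n_neighbors=spec.n_neighbors,
            metric="precomputed" if is_distance else "euclidean",
            random_state=spec.seed,
            n_jobs=1,
        )
        return np.asarray(reducer.fit_transform(x), dtype=float)


def _run_pcoa(x: np.ndarray, is_distance: bool, spec: EmbeddingSpec) -> np.ndarray:
    if not is_distance:
        x = pairwise_distances(x).values
    D = DissimilarityMatrix(x)
    cs = principal_coordinates(double_center(D), k=spec.output_dim)
    out = np.zeros((D.n, spec.output_dim))
    out[:, : cs.k] = cs.coords
    return out


_EMBEDDERS: dict[str, callable] = {}


def register_embedder(name: str, fn, overwrite: bool = False) -> None:
    """Register a dimension-reduction backend.

    ``fn(x, is_distance, spec) -> (n, output_dim) array`` must accept either a
    coordinate matrix (``is_distance=False``) or a precomputed square distance
    matrix, and must respect ``spec.seed`` if stochastic.
    """
    if name in _EMBEDDERS and not overwrite:
        raise ValueError(f"embedder {name!r} is already registered")
    _EMBEDDERS[name] = fn


def available_embedders() -> list[str]:
    return sorted(_EMBEDDERS)


register_embedder("tsne", _run_tsne)
register_embedder("umap", _run_umap)
register_embedder("pcoa", _run_pcoa)


# ---------------------------------------------------------------------------
# the partial-embedding pipeline


def _is_distance_input(data_or_D) -> bool:
    return isinstance(data_or_D, DissimilarityMatrix)


def pare_input(
    data_or_D,
    design: DesignMatrix | None = None,
    n_coords: int | None = None,
    truncate_before_adjust: bool = False,
):
    """Compute what the embedder will be fed, without running it.

    Returns an :class:`AdjustedCoordinates` on the Euclidean path (feature
    matrix in) or a :class:`DissimilarityMatrix` of adjusted distances on the
    general path (precomputed dissimilarities in).  With no design (or an
    intercept-only design) the geometry is unchanged up to centering, so the
    result reproduces the unadjusted input distances.
    """
    if _is_distance_input(data_or_D):
        D = data_or_D
        G = double_center(D)
        if design is None:
            return adjusted_distances(G)
        H = hat_matrix(design)
        delta = adjusted_gram(G, H)
        if n_coords is not None:
            cs = principal_coordinates(delta, k=n_coords)
            return pairwise_distances(cs.coords) if cs.k else adjusted_distances(delta)
        return adjusted_distances(delta)

    data = np.asarray(data_or_D, dtype=float)
    D = pairwise_distances(data)
    G = double_center(D)
    Z = principal_coordinates(G)
    adjusted_for: list[str] = []
    if design is None:
        E, eig = Z.coords, Z.eigenvalues
    else:
        H = hat_matrix(design)
        if truncate_before_adjust and n_coords is not None:
            Z = principal_coordinates(G, k=n_coords)
        adj = adjust_coordinates(Z, H, adjusted_for=design.covariate_names)
        E, eig = adj.coords, adj.source_eigenvalues
        adjusted_for = adj.adjusted_for
    if n_coords is not None and not truncate_before_adjust:
        E, eig = E[:, :n_coords], eig[:n_coords]
    return AdjustedCoordinates(E, source_eigenvalues=eig, adjusted_for=adjusted_for,
                               sample_ids=list(D.sample_ids))


def pare_embed(
    data_or_D,
    design: DesignMatrix | None = None,
    spec: EmbeddingSpec | None = None,
) -> EmbeddingResult:
    """Run a partial embedding: adjust the geometry, then embed it.

    Euclidean path (feature matrix input): principal coordinates Z are
    residualized to E = (I - H) Z, optionally truncated to ``spec.n_coords``
    columns, and passed to the embedder as input data.  General path
    (precomputed :class:`DissimilarityMatrix` input): the adjusted Gram matrix
    is converted to genuine distances and passed in precomputed-distance mode.
    An empty design yields the ordinary, unadjusted embedding.
    """
    spec = spec or EmbeddingSpec()
    if spec.method not in _EMBEDDERS:
        raise ValueError(
            f"unknown embedding method {spec.method!r}; "
            f"available: {available_embedders()}"
        )
    prepared = pare_input(
        data_or_D, design, n_coords=spec.n_coords,
        truncate_before_adjust=spec.truncate_before_adjust,
    )
    if isinstance(prepared, AdjustedCoordinates):
        n = prepared.n
        spec.validate(n)
        coords = _EMBEDDERS[spec.method](prepared.coords, False, spec)
        ids = prepared.sample_ids
        adjusted_for = prepared.adjusted_for
    else:
        n = prepared.n
        spec.validate(n)
        coords = _EMBEDDERS[spec.method](prepared.values, True, spec)
        ids = prepared.sample_ids
        adjusted_for = design.covariate_names if design is not None else []
    return EmbeddingResult(coords, spec=spec, adjusted_for=list(adjusted_for),
                           sample_ids=ids)
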