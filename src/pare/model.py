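"""Model-style front end: build once from data + metadata, fit, inspect.

:class:`PartialEmbedding` bundles the whole pipeline — pairwise distances,
principal coordinates, linear residualization against nuisance covariates,
and a choice of embedding backend — behind a fit/results pair.  The "model"
being fitted is the linear model of the nuisance covariates on the principal
coordinates; everything downstream consumes its residuals.

    >>> model = PartialEmbedding(y, metadata=meta, adjust=["batch"])
    >>> res = model.fit(method="umap", seed=0)
    >>> res.silhouette("batch", goal="mix").median
    >>> print(res.summary())
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import metrics as _metrics
from .adjustment import (
    DesignMatrix,
    adjust_coordinates,
    adjusted_gram,
    build_design,
    hat_matrix,
)
from .embedding import EmbeddingResult, EmbeddingSpec, pare_embed, pare_input
from .geometry import (
    DissimilarityMatrix,
    double_center,
    euclidify,
    pairwise_distances,
    principal_coordinates,
)

__all__ = ["PartialEmbedding", "PartialEmbeddingResults"]


class PartialEmbedding:
    """Confounder-adjusted distance-based dimension reduction.

    Parameters
    ----------
    data : array-like (n, m) or DissimilarityMatrix
        Feature matrix (Euclidean path) or precomputed dissimilarities
        (general path).
    metadata : DataFrame, optional
        Per-sample table indexed by sample ID, row-aligned to ``data``
        (aligned by ID when sample IDs are available on both sides).
    adjust : sequence of str
        Metadata columns to residualize out.  Empty = ordinary embedding.
    covariate_types : dict, optional
        Per-covariate override, ``"categorical"`` or ``"continuous"``.
    correction : {"none", "cailliez", "lingoes"}
        Additive-constant repair applied to non-Euclidean dissimilarity
        input before decomposition.
    """

    def __init__(self, data, metadata: pd.DataFrame | None = None,
                 adjust: list[str] | tuple[str, ...] = (),
                 covariate_types: dict[str, str] | None = None,
                 correction: str = "none"):
        if isinstance(data, DissimilarityMatrix):
            self.distances: DissimilarityMatrix | None = data
            self.data = None
            self.sample_ids = list(data.sample_ids)
        else:
            self.data = np.asarray(data, dtype=float)
            self.distances = None
            if metadata is not None and len(metadata) == self.data.shape[0]:
                self.sample_ids = [str(s) for s in metadata.index]
            else:
                self.sample_ids = [f"s{i}" for i in range(self.data.shape[0])]
        self.metadata = metadata
        self.adjust = list(adjust)
        self.covariate_types = covariate_types or {}
        self.correction = correction
        if self.adjust and metadata is None:
            raise ValueError("adjusting for covariates requires metadata")

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, metadata: pd.DataFrame,
                       adjust=(), **kwargs) -> "PartialEmbedding":
        """Build from a samples x features DataFrame, aligning metadata by ID."""
        ids = [str(s) for s in df.index]
        missing = [s for s in ids if s not in metadata.index.astype(str)]
        if missing:
            raise ValueError(f"metadata is missing samples: {missing}")
        meta = metadata.copy()
        meta.index = meta.index.astype(str)
        model = cls(df.to_numpy(dtype=float), metadata=meta.loc[ids],
                    adjust=list(adjust), **kwargs)
        model.sample_ids = ids
        return model

    # -- internals ---------------------------------------------------------

    def _design(self) -> DesignMatrix | None:
        if not self.adjust:
            return None
        return build_design(self.metadata, self.adjust, self.covariate_types)

    def _base_distances(self) -> DissimilarityMatrix:
        if self.distances is not None:
            D = self.distances
            if self.correction != "none":
                D = euclidify(D, method=self.correction)
            return D
        return pairwise_distances(self.data, sample_ids=self.sample_ids)

    # -- fitting -----------------------------------------------------------

    def fit(self, method: str = "umap", *, perplexity: float = 10.0,
            n_neighbors: int = 15, output_dim: int = 2, seed: int = 0,
            n_coords: int | None = None,
            truncate_before_adjust: bool = False) -> "PartialEmbeddingResults":
        """Decompose, residualize, embed; return a results object."""
        spec = EmbeddingSpec(method=method, perplexity=perplexity,
                             n_neighbors=n_neighbors, output_dim=output_dim,
                             seed=seed, n_coords=n_coords,
                             truncate_before_adjust=truncate_before_adjust)
        design = self._design()
        D = self._base_distances()
        G = double_center(D)
        Z = principal_coordinates(G)
        if design is not None:
            H = hat_matrix(design)
            E = adjust_coordinates(Z, H, adjusted_for=design.covariate_names)
            delta = adjusted_gram(G, H)
        else:
            E, delta = None, None
        source = self.data if self.data is not None else D
        embedding = pare_embed(source, design, spec)
        embedding.sample_ids = list(self.sample_ids)
        return PartialEmbeddingResults(
            model=self, embedding=embedding, principal=Z, adjusted=E,
            adjusted_gram_=delta, design=design,
            correction_constant=getattr(D, "correction_constant", 0.0),
        )


@dataclass
class PartialEmbeddingResults:
    """Fitted partial embedding: coordinates, geometry, and evaluation hooks."""

    model: PartialEmbedding
    embedding: EmbeddingResult
    principal: object  # CoordinateSet Z
    adjusted: object | None  # AdjustedCoordinates E (None if unadjusted)
    adjusted_gram_: object | None
    design: DesignMatrix | None
    correction_constant: float = 0.0

    # -- accessors ---------------------------------------------------------

    @property
    def coords(self) -> np.ndarray:
        return self.embedding.coords

    @property
    def eigenvalues(self) -> np.ndarray:
        return self.principal.eigenvalues

    def to_frame(self) -> pd.DataFrame:
        cols = [f"dim{i + 1}" for i in range(self.coords.shape[1])]
        df = pd.DataFrame(self.coords, index=self.embedding.sample_ids, columns=cols)
        df.index.name = "sample_id"
        return df

    # -- evaluation --------------------------------------------------------

    def _labels(self, label: str) -> pd.Series:
        if self.model.metadata is None or label not in self.model.metadata.columns:
            raise ValueError(f"label {label!r} not found in metadata")
        return self.model.metadata[label]

    def lisi(self, label: str, perplexity: float = 30.0,
             goal: str | None = None) -> _metrics.MetricReport:
        return _metrics.lisi(self.coords, self._labels(label),
                             perplexity=perplexity, goal=goal)

    def silhouette(self, label: str, goal: str | None = None) -> _metrics.MetricReport:
        return _metrics.silhouette(self.coords, self._labels(label), goal=goal)

    # -- reporting ---------------------------------------------------------

    def summary(self) -> str:
        Z = self.principal
        spec = self.embedding.spec
        lines = [
            "Partial Embedding Results",
            "=" * 41,
            f"samples:                 {Z.n}",
            f"retained coordinates:    {Z.k}",
            f"dropped non-positive ev: {Z.n_dropped_nonpositive}",
            f"correction constant:     {self.correction_constant:g}",
            f"method:                  {spec.method}",
            f"output dim:              {spec.output_dim}",
            f"seed:                    {spec.seed}",
        ]
        if spec.method == "tsne":
            lines.append(f"perplexity:              {spec.perplexity:g}")
        if spec.method == "umap":
            lines.append(f"n_neighbors:             {spec.n_neighbors}")
        if self.design is not None:
            lines.append(f"adjusted for:            {', '.join(self.design.covariate_names)}")
            lines.append(f"design columns (p):      {self.design.p}")
        else:
            lines.append("adjusted for:            (none)")
        ev = Z.eigenvalues
        if ev.size:
            top = ev[: min(5, ev.size)] / ev.sum()
            frac = ", ".join(f"{x:.3f}" for x in top)
            lines.append(f"top eigenvalue shares:   {frac}")
        return "\n".join(lines)

    # -- plotting ----------------------------------------------------------

    def plot(self, label: str | None = None, ax=None, **scatter_kw):
        """2-D scatter of the embedding, optionally colored by a metadata label."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(5, 5))
        xy = self.coords[:, :2]
        if label is None:
            ax.scatter(xy[:, 0], xy[:, 1], s=8, **scatter_kw)
        else:
            lab = self._labels(label).astype(str)
            for lev in sorted(lab.unique()):
                pts = xy[(lab == lev).to_numpy()]
                ax.scatter(pts[:, 0], pts[:, 1], s=8, label=lev, **scatter_kw)
            ax.legend(title=label, fontsize=8)
        ax.set_xlabel("dim1")
        ax.set_ylabel("dim2")
        title = self.embedding.spec.method
        if self.embedding.adjusted_for:
            title += f" | adjusted for {', '.join(self.embedding.adjusted_for)}"
        ax.set_title(title)
        return ax
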