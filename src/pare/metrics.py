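"""Embedding evaluation: local inverse Simpson's index and silhouette width.

LISI measures the effective number of categories (batches, cell types, sites,
subjects) in the weighted neighborhood of each sample: Gaussian neighbor
weights are calibrated to a target perplexity exactly as in t-SNE, summed
into per-category probabilities p_c, and inverted through the Simpson index,
LISI_i = 1 / sum_c p_c^2.  A value of 1 means the neighborhood is pure; C
means the C categories are perfectly mixed.

The silhouette width s_i = (b_i - a_i) / max(a_i, b_i) compares the mean
distance to a sample's own category (a_i) with the nearest other category
(b_i); the average over samples (ASW) is a global separation statistic in
[-1, 1].  Whether "better" is high or low depends on the label: a batch label
should mix (high LISI, low ASW) while a biological label should separate
(low LISI, high ASW).

Both metrics are summarized the same way throughout this package: median,
2.5% quantile, and 97.5% quantile of the per-sample values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .embedding import _tsne_row

__all__ = ["LabelVector", "MetricReport", "lisi", "lisi_sweep", "silhouette"]


@dataclass
class LabelVector:
    """A categorical per-sample label (batch, cell type, site, ...)."""

    labels: np.ndarray
    name: str = "label"

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.size == 0:
            raise ValueError("label vector is empty")

    @property
    def categories(self) -> np.ndarray:
        return np.unique(self.labels)

    @property
    def n_categories(self) -> int:
        return self.categories.size


_DIRECTIONS = {
    ("lisi", "mix"): "higher is better (greater integration)",
    ("lisi", "separate"): "lower is better (greater separation)",
    ("silhouette", "mix"): "lower is better (greater integration)",
    ("silhouette", "separate"): "higher is better (greater separation)",
}


@dataclass
class MetricReport:
    """Per-sample metric values with median / 2.5% / 97.5% summaries."""

    per_sample: np.ndarray
    metric: str  # "lisi" | "silhouette"
    label_name: str
    parameters: dict = field(default_factory=dict)
    direction: str | None = None

    def __post_init__(self) -> None:
        self.per_sample = np.asarray(self.per_sample, dtype=float)

    @property
    def median(self) -> float:
        return float(np.median(self.per_sample))

    @property
    def quantile_2_5(self) -> float:
        return float(np.quantile(self.per_sample, 0.025))

    @property
    def quantile_97_5(self) -> float:
        return float(np.quantile(self.per_sample, 0.975))

    @property
    def summary(self) -> dict:
        return {
            "median": self.median,
            "quantile_2.5": self.quantile_2_5,
            "quantile_97.5": self.quantile_97_5,
        }

    def to_dict(self) -> dict:
        out = {
            "metric": self.metric,
            "label": self.label_name,
            "per_sample": self.per_sample.tolist(),
            **self.summary,
        }
        if self.parameters:
            out["parameters"] = dict(self.parameters)
        if self.direction:
            out["direction"] = self.direction
        return out


def _resolve_labels(labels) -> LabelVector:
    if isinstance(labels, LabelVector):
        return labels
    if isinstance(labels, pd.Series):
        return LabelVector(labels.to_numpy(), name=str(labels.name or "label"))
    return LabelVector(np.asarray(labels))


def lisi(
    embedding: np.ndarray,
    labels,
    perplexity: float = 30.0,
    goal: str | None = None,
) -> MetricReport:
    """Per-sample local inverse Simpson's index of a label in an embedding.

    Gaussian weights over all other samples are calibrated by bisection so
    each sample's neighbor distribution has entropy log2(perplexity) (the
    t-SNE conditional contract, self excluded), aggregated per category and
    inverted through the Simpson index.  Values lie in [1, n_categories].

    ``goal`` ("mix" or "separate") records which direction counts as better
    for this label in the report.
    """
    lab = _resolve_labels(labels)
    x = np.atleast_2d(np.asarray(embedding, dtype=float))
    n = x.shape[0]
    if lab.labels.shape[0] != n:
        raise ValueError("labels length does not match embedding")
    if lab.n_categories == 1:
        vals = np.ones(n)
    else:
        if not (1 < perplexity < n):
            raise ValueError(f"perplexity must be in (1, n={n}), got {perplexity}")
        d2 = squareform(pdist(x)) ** 2
        codes = pd.factorize(lab.labels)[0]
        n_cat = codes.max() + 1
        target = np.log2(perplexity)
        vals = np.empty(n)
        for i in range(n):
            mask = np.arange(n) != i
            row = d2[i, mask]
            if np.all(row == row[0]):
                p = np.full(n - 1, 1.0 / (n - 1))
            else:
                p, _ = _tsne_row(row, target)
            p_cat = np.bincount(codes[mask], weights=p, minlength=n_cat)
            vals[i] = 1.0 / np.sum(p_cat**2)
    direction = _DIRECTIONS.get(("lisi", goal)) if goal else None
    return MetricReport(vals, metric="lisi", label_name=lab.name,
                        parameters={"perplexity": perplexity}, direction=direction)


def lisi_sweep(embedding, labels, perplexities, goal: str | None = None
               ) -> list[MetricReport]:
    """LISI across a list of perplexities (neighborhood sizes)."""
    return [lisi(embedding, labels, perplexity=p, goal=goal) for p in perplexities]


def silhouette(embedding: np.ndarray, labels, goal: str | None = None) -> MetricReport:
    """Per-sample silhouette widths of a label in an embedding.

    Euclidean distances in the supplied coordinate space; samples whose label
    has a single member get s_i = 0 by convention.  Requires at least two
    categories.
    """
    from sklearn.metrics import silhouette_samples

    lab = _resolve_labels(labels)
    x = np.atleast_2d(np.asarray(embedding, dtype=float))
    if lab.labels.shape[0] != x.shape[0]:
        raise ValueError("labels length does not match embedding")
    if lab.n_categories < 2:
        raise ValueError("silhouette requires at least 2 label categories")
    vals = silhouette_samples(x, lab.labels.astype(str), metric="euclidean")
    direction = _DIRECTIONS.get(("silhouette", goal)) if goal else None
    return MetricReport(np.asarray(vals, dtype=float), metric="silhouette",
                        label_name=lab.name, direction=direction)
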