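"""Synthetic datasets with group structure, batch shifts and confounders.

The generator emulates the structure of multi-batch omics and imaging
studies: biological groups (cell types, diagnoses) give clustered mean
vectors, acquisition batches (study, scanner, site) add a shared additive
shift, an optional continuous confounder loads linearly on every feature,
and residual variation is isotropic Gaussian:

    y_i = mu_group(i) + gamma_batch(i) + beta * c_i + eps_i .

Group means and batch shifts are drawn once per level from isotropic
Gaussians scaled by ``group_effect`` and ``batch_effect``; there is no
group x batch interaction by default, so linear residualization against
batch is exactly the right model (an ``interaction`` dial exists to probe
misspecification).  Everything is a deterministic function of the seed, and
the generating effects are returned so tests can reconstruct the batch-free
data exactly.

A count-flavored variant (:func:`scrnaseq_like`) draws Poisson-log-normal
counts with group-specific log-means and batch-specific log-shifts and
log1p-normalizes them, mirroring a pooled single-cell RNA-seq resource with
13 cell types across 4 studies.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = ["SyntheticConfig", "SyntheticDataset", "generate", "scrnaseq_like"]


@dataclass(frozen=True)
class SyntheticConfig:
    """Dials of the generator; defaults give a batch-dominated desk-scale study.

    ``batch_effect`` defaults to three times ``group_effect`` so that, as in
    real pooled studies, the unwanted shift dominates the biology until it is
    adjusted away.
    """

    n_per_cell: int = 30
    n_groups: int = 5
    n_batches: int = 4
    n_features: int = 50
    group_effect: float = 1.0
    batch_effect: float = 3.0
    continuous_confounder_slope: float = 0.0
    noise_sd: float = 0.5
    interaction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_per_cell, self.n_groups, self.n_batches, self.n_features) < 1:
            raise ValueError("all counts must be >= 1")
        if self.noise_sd < 0 or self.group_effect < 0 or self.batch_effect < 0:
            raise ValueError("effect scales and noise_sd must be >= 0")

    @property
    def n_samples(self) -> int:
        return self.n_per_cell * self.n_groups * self.n_batches


@dataclass
class SyntheticDataset:
    """Features, aligned metadata, and the generating truth."""

    features: np.ndarray
    metadata: pd.DataFrame
    truth: dict = field(default_factory=dict)
    counts: np.ndarray | None = None

    @property
    def n(self) -> int:
        return self.features.shape[0]

    def reconstruct(self) -> np.ndarray:
        """Rebuild the feature matrix from the stored truth, bit for bit."""
        t = self.truth
        y = (
            t["group_means"][t["group_codes"]]
            + t["batch_shifts"][t["batch_codes"]]
            + np.outer(t["confounder"], t["confounder_loadings"])
            + t["noise"]
        )
        if t.get("interaction_terms") is not None:
            y = y + t["interaction_terms"]
        return y

    def batch_free_features(self) -> np.ndarray:
        """Remove the known batch shifts and confounder term from the features."""
        g = self.truth["batch_shifts"][self.truth["batch_codes"]]
        out = self.features - g
        beta = self.truth.get("confounder_loadings")
        if beta is not None:
            out = out - np.outer(self.truth["confounder"], beta)
        return out


def _assignments(cfg: SyntheticConfig) -> tuple[np.ndarray, np.ndarray]:
    # balanced crossing: every (group, batch) cell has n_per_cell samples
    groups = np.repeat(np.arange(cfg.n_groups), cfg.n_batches * cfg.n_per_cell)
    batches = np.tile(np.repeat(np.arange(cfg.n_batches), cfg.n_per_cell), cfg.n_groups)
    return groups, batches


def generate(cfg: SyntheticConfig) -> SyntheticDataset:
    """Draw a Gaussian dataset y = mu_group + gamma_batch + beta*c + eps."""
    rng = np.random.default_rng(cfg.seed)
    groups, batches = _assignments(cfg)
    n, m = cfg.n_samples, cfg.n_features

    mu = rng.normal(0.0, 1.0, size=(cfg.n_groups, m)) * cfg.group_effect
    gamma = rng.normal(0.0, 1.0, size=(cfg.n_batches, m)) * cfg.batch_effect
    conf = rng.normal(0.0, 1.0, size=n)
    beta = rng.normal(0.0, 1.0, size=m) * cfg.continuous_confounder_slope
    eps = rng.normal(0.0, cfg.noise_sd, size=(n, m))

    y = mu[groups] + gamma[batches] + np.outer(conf, beta) + eps
    inter_terms = None
    if cfg.interaction:
        inter = rng.normal(0.0, cfg.interaction,
                           size=(cfg.n_groups, cfg.n_batches, m))
        inter_terms = inter[groups, batches]
        y = y + inter_terms

    meta = pd.DataFrame(
        {
            "group": pd.Categorical([f"g{g}" for g in groups]),
            "batch": pd.Categorical([f"b{b}" for b in batches]),
            "confounder": conf,
        },
        index=pd.Index([f"s{i:04d}" for i in range(n)], name="sample_id"),
    )
    truth = {
        "group_means": mu,
        "batch_shifts": gamma,
        "confounder_loadings": beta,
        "confounder": conf,
        "group_codes": groups,
        "batch_codes": batches,
        "noise": eps,
        "interaction_terms": inter_terms,
        "config": cfg,
    }
    return SyntheticDataset(features=y, metadata=meta, truth=truth)


def scrnaseq_like(cfg: SyntheticConfig | None = None) -> SyntheticDataset:
    """Poisson-log-normal counts with batch log-shifts, then log1p-normalized.

    Defaults mirror the category structure of a pooled pancreatic single-cell
    resource: 13 cell types ("groups") across 4 studies ("batches").  The
    returned ``features`` are log1p counts; raw counts are kept in ``counts``.
    """
    if cfg is None:
        cfg = SyntheticConfig(n_per_cell=20, n_groups=13, n_batches=4,
                              n_features=100, group_effect=1.0,
                              batch_effect=0.5, noise_sd=0.3)
    rng = np.random.default_rng(cfg.seed)
    groups, batches = _assignments(cfg)
    n, m = cfg.n_samples, cfg.n_features

    base = rng.normal(1.0, 0.5, size=m)  # per-gene baseline log-mean
    mu = rng.normal(0.0, 1.0, size=(cfg.n_groups, m)) * cfg.group_effect
    gamma = rng.normal(0.0, 1.0, size=(cfg.n_batches, m)) * cfg.batch_effect
    eps = rng.normal(0.0, cfg.noise_sd, size=(n, m))

    log_mean = base + mu[groups] + gamma[batches] + eps
    counts = rng.poisson(np.exp(log_mean)).astype(np.int64)
    features = np.log1p(counts.astype(float))

    meta = pd.DataFrame(
        {
            "group": pd.Categorical([f"g{g}" for g in groups]),
            "batch": pd.Categorical([f"b{b}" for b in batches]),
        },
        index=pd.Index([f"cell{i:05d}" for i in range(n)], name="sample_id"),
    )
    truth = {
        "baseline_log_means": base,
        "group_log_means": mu,
        "batch_log_shifts": gamma,
        "group_codes": groups,
        "batch_codes": batches,
        "config": cfg,
    }
    return SyntheticDataset(features=features, metadata=meta, truth=truth,
                            counts=counts)
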