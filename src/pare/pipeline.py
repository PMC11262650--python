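"""End-to-end runs: read inputs, embed (adjusted and optionally unadjusted),
score, and write artifacts plus a reproducibility manifest."""

from __future__ import annotations

import json
import platform
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .io import (
    align_metadata,
    read_distances,
    read_features,
    read_metadata,
    write_embedding_csv,
)
from .metrics import lisi_sweep, silhouette
from .model import PartialEmbedding

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """Everything a run needs; a manifest of these values reproduces it."""

    input_path: str
    metadata_path: str | None = None
    input_kind: str = "features"  # features | distances | mtx
    adjust: list[str] = field(default_factory=list)
    covariate_types: dict[str, str] = field(default_factory=dict)
    method: str = "umap"
    perplexity: float = 10.0
    n_neighbors: int = 15
    output_dim: int = 2
    seed: int = 0
    n_coords: int | None = None
    baseline: bool = False  # also emit the unadjusted embedding
    metric_labels: list[str] = field(default_factory=list)
    lisi_perplexities: list[float] = field(default_factory=lambda: [30.0])
    out_dir: str = "pare_out"

    def to_manifest(self) -> dict:
        d = {k: v for k, v in self.__dict__.items()}
        return d


def _build_model(cfg: RunConfig, adjust: list[str]) -> PartialEmbedding:
    if cfg.input_kind == "distances":
        D = read_distances(cfg.input_path)
        meta = None
        if cfg.metadata_path:
            meta = align_metadata(read_metadata(cfg.metadata_path), list(D.sample_ids))
        return PartialEmbedding(D, metadata=meta, adjust=adjust,
                                covariate_types=cfg.covariate_types)
    fmt = "mtx" if cfg.input_kind == "mtx" else None
    mat, ids, _ = read_features(cfg.input_path, fmt=fmt)
    meta = None
    if cfg.metadata_path:
        meta = align_metadata(read_metadata(cfg.metadata_path), ids)
    model = PartialEmbedding(mat, metadata=meta, adjust=adjust,
                             covariate_types=cfg.covariate_types)
    model.sample_ids = ids
    return model


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute a configured run; returns the manifest (also written to disk)."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": cfg.to_manifest(),
        "versions": {
            "pare": __version__,
            "python": platform.python_version(),
            "numpy": np.__version__,
        },
        "outputs": {},
        "status": "incomplete",
    }
    manifest_path = out / "manifest.json"
    try:
        runs = [("adjusted" if cfg.adjust else "embedding", cfg.adjust)]
        if cfg.baseline and cfg.adjust:
            runs.append(("unadjusted", []))
        results = {}
        for tag, adjust in runs:
            model = _build_model(cfg, adjust)
            res = model.fit(method=cfg.method, perplexity=cfg.perplexity,
                            n_neighbors=cfg.n_neighbors, output_dim=cfg.output_dim,
                            seed=cfg.seed, n_coords=cfg.n_coords)
            path = out / f"{tag}.csv"
            write_embedding_csv(path, res.embedding)
            results[tag] = res
            manifest["outputs"][tag] = str(path)
            ev = res.eigenvalues
            manifest[f"{tag}_geometry"] = {
                "n": int(res.principal.n),
                "retained_coordinates": int(res.principal.k),
                "dropped_nonpositive_eigenvalues": int(res.principal.n_dropped_nonpositive),
                "correction_constant": float(res.correction_constant),
                "eigenvalue_sum": float(ev.sum()) if ev.size else 0.0,
                "top_eigenvalues": [float(x) for x in ev[:10]],
            }

        if cfg.metric_labels:
            scores: dict = {}
            for tag, res in results.items():
                scores[tag] = {}
                for label in cfg.metric_labels:
                    lab = res._labels(label)
                    reports = lisi_sweep(res.coords, lab, cfg.lisi_perplexities)
                    scores[tag][label] = {
                        "lisi": [
                            {"perplexity": r.parameters["perplexity"], **r.summary}
                            for r in reports
                        ],
                        "silhouette": silhouette(res.coords, lab).summary,
                    }
            metrics_path = out / "metrics.json"
            metrics_path.write_text(json.dumps(scores, indent=1))
            manifest["outputs"]["metrics"] = str(metrics_path)

        manifest["seed"] = cfg.seed
        manifest["status"] = "ok"
        return manifest
    finally:
        manifest_path.write_text(json.dumps(manifest, indent=1))
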