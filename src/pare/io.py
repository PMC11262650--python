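"""Readers and writers for feature matrices, distances, metadata and results.

Supported feature inputs: dense CSV/TSV (header row = feature names, first
column = sample IDs) and MatrixMarket triplet files with two sibling
plain-text line files for row (sample/barcode) and column (gene) names —
``<stem>.mtx`` + ``<stem>.rows.txt`` + ``<stem>.cols.txt`` by default, the
usual single-cell convention.  Precomputed dissimilarities are square CSV/TSV
with identical row and column orderings.  Sample alignment between features
and metadata is always by ID, never by position.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.io import mmread, mmwrite

from .geometry import DissimilarityMatrix

__all__ = [
    "read_features",
    "read_metadata",
    "read_distances",
    "write_features_csv",
    "write_features_mtx",
    "write_embedding_csv",
    "write_dataset",
    "align_metadata",
]


def _sep_for(path: Path) -> str:
    return "\t" if path.suffix.lower() in {".tsv", ".tab", ".txt"} else ","


def read_features(path, fmt: str | None = None) -> tuple[np.ndarray, list[str], list[str]]:
    """Read a samples x features matrix.

    Returns ``(matrix, sample_ids, feature_names)``.  ``fmt`` is inferred
    from the extension (``csv``/``tsv`` dense, ``mtx`` MatrixMarket triplet
    with ``.rows.txt`` / ``.cols.txt`` siblings) unless given.
    """
    path = Path(path)
    fmt = fmt or ("mtx" if path.suffix.lower() == ".mtx" else "dense")
    if fmt == "mtx":
        mat = mmread(path)
        if sparse.issparse(mat):
            mat = mat.toarray()
        mat = np.asarray(mat, dtype=float)
        rows_file = path.parent / (path.stem + ".rows.txt")
        cols_file = path.parent / (path.stem + ".cols.txt")
        sample_ids = rows_file.read_text().splitlines()
        feature_names = cols_file.read_text().splitlines()
        if len(sample_ids) != mat.shape[0] or len(feature_names) != mat.shape[1]:
            raise ValueError(
                f"name files do not match matrix shape {mat.shape}: "
                f"{len(sample_ids)} row names, {len(feature_names)} column names"
            )
    else:
        df = pd.read_csv(path, sep=_sep_for(path), index_col=0,
                         float_precision="round_trip")
        mat = df.to_numpy(dtype=float)
        sample_ids = [str(s) for s in df.index]
        feature_names = [str(c) for c in df.columns]
    dup = pd.Index(sample_ids).duplicated()
    if dup.any():
        dups = sorted(set(np.asarray(sample_ids)[dup].tolist()))
        raise ValueError(f"duplicate sample IDs: {dups}")
    return mat, sample_ids, feature_names


def read_metadata(path) -> pd.DataFrame:
    """Read the per-sample metadata table, indexed by its first column."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path), index_col=0,
                     float_precision="round_trip")
    df.index = df.index.astype(str)
    if df.index.duplicated().any():
        dups = sorted(set(df.index[df.index.duplicated()]))
        raise ValueError(f"duplicate sample IDs in metadata: {dups}")
    return df


def align_metadata(metadata: pd.DataFrame, sample_ids: list[str]) -> pd.DataFrame:
    """Reorder metadata rows to the feature-matrix sample order, by ID."""
    missing = [s for s in sample_ids if s not in metadata.index]
    if missing:
        raise ValueError(f"metadata is missing samples: {missing}")
    return metadata.loc[sample_ids]


def read_distances(path) -> DissimilarityMatrix:
    """Read a precomputed square dissimilarity matrix (CSV/TSV)."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path), index_col=0,
                     float_precision="round_trip")
    ids = [str(s) for s in df.index]
    if [str(c) for c in df.columns] != ids:
        raise ValueError("row and column IDs of the distance matrix differ")
    return DissimilarityMatrix(df.to_numpy(dtype=float), metric_name="precomputed",
                               sample_ids=ids)


def write_features_csv(path, matrix, sample_ids, feature_names) -> None:
    df = pd.DataFrame(np.asarray(matrix), index=sample_ids, columns=feature_names)
    df.index.name = "sample_id"
    df.to_csv(path, sep=_sep_for(Path(path)), float_format="%.17g")


def write_features_mtx(path, matrix, sample_ids, feature_names) -> None:
    path = Path(path)
    mmwrite(path, sparse.coo_matrix(np.asarray(matrix)))
    (path.parent / (path.stem + ".rows.txt")).write_text(
        "\n".join(map(str, sample_ids)) + "\n")
    (path.parent / (path.stem + ".cols.txt")).write_text(
        "\n".join(map(str, feature_names)) + "\n")


def write_embedding_csv(path, result) -> None:
    """Write an EmbeddingResult as sample_id,dim1,dim2,... with full precision."""
    cols = [f"dim{i + 1}" for i in range(result.coords.shape[1])]
    df = pd.DataFrame(result.coords, index=result.sample_ids, columns=cols)
    df.index.name = "sample_id"
    df.to_csv(path, float_format="%.17g")


def write_dataset(dataset, out_dir) -> dict[str, str]:
    """Emit a SyntheticDataset as features.csv, features.mtx (+ name files),
    metadata.csv and truth.json; returns the paths written."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ids = [str(s) for s in dataset.metadata.index]
    feats = [f"f{j}" for j in range(dataset.features.shape[1])]
    write_features_csv(out / "features.csv", dataset.features, ids, feats)
    write_features_mtx(out / "features.mtx", dataset.features, ids, feats)
    dataset.metadata.to_csv(out / "metadata.csv")
    truth = {
        k: (v.tolist() if isinstance(v, np.ndarray) else str(v))
        for k, v in dataset.truth.items()
        if k != "noise" and v is not None
    }
    (out / "truth.json").write_text(json.dumps(truth, indent=1))
    return {
        "features_csv": str(out / "features.csv"),
        "features_mtx": str(out / "features.mtx"),
        "metadata": str(out / "metadata.csv"),
        "truth": str(out / "truth.json"),
    }
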