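"""Dimensionality reduction over region-table columns.

Any set of numeric columns can be assembled into a feature matrix
(optionally z-scored, or log1p-then-z-scored for heavy-tailed signal
areas) and reduced with UMAP or t-SNE to ``n_dims`` output dimensions
(default 2).  The coordinates are attached back to the table as columns
``<prefix>1..<prefix>k``, so dimensions from different algorithms can be
mixed and matched in downstream scatter configurations.

Rows with a missing value in any chosen column are excluded from the fit
and get missing coordinates.  Both algorithms are run with a fixed seed
and are deterministic for fixed input.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass
from typing import Literal, Sequence

import numpy as np

from .regions import RegionTable

logger = logging.getLogger(__name__)

__all__ = [
    "EmbeddingConfig",
    "EmbeddingResult",
    "build_feature_matrix",
    "run_embedding",
    "attach_embedding",
    "embed_table",
]

MIN_ROWS = 10


@dataclass
class EmbeddingConfig:
    columns: Sequence[str]
    algorithm: Literal["umap", "tsne"] = "umap"
    n_dims: int = 2
    seed: int = 42
    scaling: Literal["zscore", "log1p_zscore", "none"] = "zscore"
    n_neighbors: int = 15          # umap
    min_dist: float = 0.1          # umap
    perplexity: float = 30.0       # tsne

    def __post_init__(self) -> None:
        if self.n_dims < 1:
            raise ValueError("n_dims must be >= 1")
        if not self.columns:
            raise ValueError("at least one input column is required")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["columns"] = list(self.columns)
        return d


@dataclass
class EmbeddingResult:
    coordinates: np.ndarray          # n_used x n_dims
    used_row_ids: list[int]
    excluded_row_ids: list[int]
    config: EmbeddingConfig

    def __post_init__(self) -> None:
        if self.coordinates.shape[0] != len(self.used_row_ids):
            raise ValueError("coordinate rows must match used_row_ids")


def build_feature_matrix(
    table: RegionTable,
    columns: Sequence[str],
    scaling: Literal["zscore", "log1p_zscore", "none"] = "zscore",
) -> tuple[np.ndarray, list[int]]:
    """Assemble (matrix, used_row_ids) from numeric columns.

    Rows with any missing value in the chosen columns are dropped.
    ``zscore`` standardises each column ((x - mean) / sd), mapping
    zero-variance columns to all zeros; ``log1p_zscore`` applies
    ``log(1+x)`` first and raises (naming the column) on negative input.
    """
    cols = [table.numeric(c) for c in columns]
    mat = np.column_stack(cols)
    complete = np.all(np.isfinite(mat), axis=1)
    used_ids = [int(i) for i in np.asarray(table.df.index)[complete]]
    mat = mat[complete]
    if scaling == "log1p_zscore":
        for j, name in enumerate(columns):
            if np.any(mat[:, j] < 0):
                raise ValueError(f"log1p_zscore requires non-negative values; column {name!r} has negatives")
        mat = np.log1p(mat)
    if scaling in ("zscore", "log1p_zscore"):
        mean = mat.mean(axis=0)
        sd = mat.std(axis=0)
        sd_safe = np.where(sd > 0, sd, 1.0)
        mat = (mat - mean) / sd_safe
        mat[:, sd == 0] = 0.0
    return mat, used_ids


def run_embedding(matrix: np.ndarray, config: EmbeddingConfig,
                  used_row_ids: Sequence[int] | None = None) -> EmbeddingResult:
    """Run UMAP or t-SNE on a prepared feature matrix.

    Parameters that are invalid for a small n (perplexity, n_neighbors)
    are clamped with a logged warning.  Fewer than 10 rows is an error:
    neighbour graphs are meaningless below that.
    """
    n = matrix.shape[0]
    if n < MIN_ROWS:
        raise ValueError(f"need at least {MIN_ROWS} rows to embed, got {n}")
    if used_row_ids is None:
        used_row_ids = list(range(1, n + 1))
    if config.algorithm == "umap":
        import umap

        n_neighbors = int(min(max(2, config.n_neighbors), n - 1))
        if n_neighbors != config.n_neighbors:
            logger.warning("clamped n_neighbors from %s to %s", config.n_neighbors, n_neighbors)
        reducer = umap.UMAP(
            n_components=config.n_dims,
            n_neighbors=n_neighbors,
            min_dist=config.min_dist,
            random_state=config.seed,
            transform_seed=config.seed,
        )
        coords = reducer.fit_transform(matrix)
    elif config.algorithm == "tsne":
        from sklearn.manifold import TSNE

        max_perp = (n - 1) / 3
        perplexity = float(min(config.perplexity, np.nextafter(max_perp, 0)))
        if perplexity != config.perplexity:
            logger.warning("clamped perplexity from %s to %s", config.perplexity, perplexity)
        method = "barnes_hut" if config.n_dims <= 3 else "exact"
        tsne = TSNE(
            n_components=config.n_dims,
            perplexity=perplexity,
            random_state=config.seed,
            init="pca",
            method=method,
        )
        coords = tsne.fit_transform(matrix)
    else:
        raise ValueError(f"unknown algorithm {config.algorithm!r}")
    coords = np.asarray(coords, dtype=float)
    if not np.all(np.isfinite(coords)):
        raise RuntimeError("embedding produced non-finite coordinates")
    return EmbeddingResult(coords, list(used_row_ids), [], config)


def attach_embedding(
    table: RegionTable,
    result: EmbeddingResult,
    prefix: str,
    overwrite: bool = False,
) -> RegionTable:
    """Attach embedding coordinates as columns ``<prefix>1..<prefix>k``.

    Rows excluded from the fit get missing values.  Raises on a column
    collision unless ``overwrite``.
    """
    ids = set(table.df.index)
    if not set(result.used_row_ids) <= ids:
        raise ValueError("embedding rows are not a subset of the table's row ids")
    k = result.coordinates.shape[1]
    for d in range(1, k + 1):
        name = f"{prefix}{d}"
        if table.has_column(name) and not overwrite:
            raise ValueError(f"column {name!r} already exists (pass overwrite=True)")
    id_to_pos = {rid: i for i, rid in enumerate(result.used_row_ids)}
    for d in range(1, k + 1):
        col = np.full(len(table), np.nan)
        for i, rid in enumerate(table.df.index):
            pos = id_to_pos.get(int(rid))
            if pos is not None:
                col[i] = result.coordinates[pos, d - 1]
        table.df[f"{prefix}{d}"] = col
    return table


def embed_table(
    table: RegionTable, config: EmbeddingConfig, prefix: str | None = None,
    overwrite: bool = False,
) -> tuple[RegionTable, EmbeddingResult]:
    """Convenience wrapper: build matrix, run the algorithm, attach columns."""
    matrix, used = build_feature_matrix(table, config.columns, config.scaling)
    result = run_embedding(matrix, config, used)
    excluded = sorted(set(map(int, table.df.index)) - set(used))
    result.excluded_row_ids = excluded
    if prefix is None:
        prefix = "UMAP" if config.algorithm == "umap" else "tSNE"
    attach_embedding(table, result, prefix, overwrite=overwrite)
    return table, result
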