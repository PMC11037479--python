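"""Chunk-parallel metacell identification pipeline.

The pipeline partitions the cell-by-region matrix into chunks of ``c``
cells, processes every chunk independently (binarize → region filter →
TF-IDF → PCA → kNN graph → Walktrap), aggregates each community into a
metacell by averaging the members' *raw* counts over the full region axis,
and finally concatenates the per-chunk metacells in chunk order.

The resolution γ is the intended ratio of cells to metacells: a chunk of
``n_i`` cells is cut at ⌈n_i/γ⌉ communities (ceiling, so every chunk yields
at least one metacell).  Up to ``m`` chunks are processed concurrently;
because every chunk is deterministic given the configuration and results
are assembled in chunk order, the output is identical for any ``m``.
"""

from __future__ import annotations

import logging
import math
import os
import tempfile
from collections import Counter
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Mapping, Sequence

import anndata as ad
import numpy as np
import scipy.sparse as sp
from joblib import Parallel, delayed

from .io import (
    BackedMatrix,
    ChunkSpec,
    MetacellMatrix,
    concatenate_metacells,
    load_chunk,
    open_backed,
    partition_into_chunks,
)
from .preprocess import binarize, build_neighbor_graph, filter_regions_chunk, pca_embed, tfidf_transform
from .walktrap import CommunityPartition, walktrap_partition

__all__ = [
    "PipelineConfig",
    "aggregate_chunk",
    "target_communities",
    "annotate_metacells",
    "process_chunk",
    "run_pipeline",
]

logger = logging.getLogger("carousel")


@dataclass(frozen=True)
class PipelineConfig:
    """All tunables of the metacell pipeline.

    chunk_size : cells per chunk (c).
    n_workers : maximum concurrently processed chunks (m).
    resolution : cells per metacell (γ > 1); each chunk is cut at ⌈n_i/γ⌉
        communities.
    k_neighbors, n_components, walk_length, frac_region_filter : the
        per-chunk preprocessing and Walktrap parameters.
    """

    chunk_size: int = 10_000
    n_workers: int = 1
    resolution: float = 75.0
    k_neighbors: int = 15
    n_components: int = 50
    walk_length: int = 4
    frac_region_filter: float = 0.01
    tfidf_variant: str = "rownorm-log1p-idf"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.resolution <= 1:
            raise ValueError(f"resolution must be > 1, got {self.resolution}")
        if self.chunk_size < self.resolution:
            raise ValueError(
                f"chunk_size ({self.chunk_size}) must be >= resolution ({self.resolution}) "
                "so each chunk yields at least one metacell"
            )
        if self.n_workers < 1:
            raise ValueError("n_workers must be >= 1")


def target_communities(chunk_cells: int, resolution: float) -> int:
    """⌈chunk_cells / γ⌉, never below 1."""
    if chunk_cells < 1:
        raise ValueError("chunk must contain at least one cell")
    if resolution <= 1:
        raise ValueError("resolution must be > 1")
    return max(1, math.ceil(chunk_cells / resolution))


def aggregate_chunk(
    X_raw: sp.spmatrix,
    partition: CommunityPartition,
    cell_ids: Sequence[str],
    region_ids: Sequence[str],
    chunk_index: int = 0,
) -> MetacellMatrix:
    """Average the raw count rows of each community into one metacell row.

    Aggregation uses the raw (unfiltered, unbinarized) counts over the full
    global region axis; the output rows are exact arithmetic means, so the
    total count mass is recoverable as Σ size_j × row_j.
    """
    X_raw = sp.csr_matrix(X_raw, dtype=np.float64)
    n = X_raw.shape[0]
    if partition.assignment.shape[0] != n:
        raise ValueError(
            f"partition covers {partition.assignment.shape[0]} cells but the matrix has {n} rows"
        )
    K = partition.n_communities
    rows = partition.assignment
    indicator = sp.coo_matrix((np.ones(n), (rows, np.arange(n))), shape=(K, n)).tocsr()
    sizes = np.asarray(indicator.sum(axis=1)).ravel()
    values = sp.diags(1.0 / sizes) @ (indicator @ X_raw)
    members = [[cell_ids[i] for i in np.flatnonzero(rows == k)] for k in range(K)]
    return MetacellMatrix(
        values=values.tocsr(),
        region_ids=list(region_ids),
        members=members,
        chunk_of=[chunk_index] * K,
    )


def annotate_metacells(
    members: Sequence[Sequence[str]],
    labels: Mapping[str, str],
) -> list[str]:
    """Label each metacell with the dominant type among its member cells.

    Ties are broken by the lexicographically smallest label.
    """
    out: list[str] = []
    for group in members:
        if not group:
            raise ValueError("empty metacell")
        try:
            counts = Counter(labels[m] for m in group)
        except KeyError as exc:
            raise ValueError(f"unlabeled member cell: {exc}") from exc
        top = max(counts.values())
        out.append(min(lab for lab, cnt in counts.items() if cnt == top))
    return out


def process_chunk(spec: ChunkSpec, config: PipelineConfig) -> MetacellMatrix:
    """Run the full per-chunk pipeline on one serialized chunk."""
    chunk = load_chunk(spec)
    n_i = chunk.n_obs
    X_raw = sp.csr_matrix(chunk.X)

    B = binarize(X_raw)
    Bf = filter_regions_chunk(B, c=n_i, frac=config.frac_region_filter)
    logger.info("chunk %d: %d cells, %d/%d regions retained", spec.index, n_i, Bf.shape[1], B.shape[1])

    k_target = target_communities(n_i, config.resolution)
    if Bf.shape[1] == 0 or n_i < 2 or k_target >= n_i:
        # degenerate chunk: nothing to merge on — every cell is its own metacell
        partition = CommunityPartition(assignment=np.arange(n_i))
    else:
        T = tfidf_transform(Bf)
        E = pca_embed(T, n_components=config.n_components, seed=config.seed)
        k = min(config.k_neighbors, n_i - 1)
        graph = build_neighbor_graph(E, k=k, seed=config.seed)
        partition = walktrap_partition(graph, target_k=k_target, l=config.walk_length)

    mc = aggregate_chunk(
        X_raw,
        partition,
        cell_ids=list(chunk.obs_names),
        region_ids=list(chunk.var_names),
        chunk_index=spec.index,
    )
    logger.info("chunk %d: %d metacells", spec.index, mc.n_metacells)
    return mc


def run_pipeline(
    input_path: str | os.PathLike,
    config: PipelineConfig,
    out_path: str | os.PathLike | None = None,
    work_dir: str | os.PathLike | None = None,
) -> ad.AnnData:
    """Partition → per-chunk metacell identification → concatenation.

    At most ``config.n_workers`` chunks are in flight at once; the combined
    output is identical for any worker count.  Member cell identifiers are
    stored in ``obs["members"]`` (delimiter-joined), along with each
    metacell's size and source chunk; the full configuration is recorded in
    ``uns["carousel_config"]``.
    """
    input_path = Path(input_path)
    cleanup = work_dir is None
    tmp = tempfile.TemporaryDirectory(prefix="carousel_") if cleanup else None
    work = Path(tmp.name) if cleanup else Path(work_dir)
    try:
        with open_backed(input_path) as X:
            specs = partition_into_chunks(X, config.chunk_size, work)
        logger.info("partitioned %s into %d chunks of size %d", input_path, len(specs), config.chunk_size)
        try:
            results: list[MetacellMatrix] = Parallel(n_jobs=config.n_workers)(
                delayed(process_chunk)(spec, config) for spec in specs
            )
        except Exception as exc:
            raise RuntimeError(f"chunk processing failed: {exc}") from exc
        combined = concatenate_metacells(results)
    finally:
        if tmp is not None:
            tmp.cleanup()

    adata = combined.to_anndata()
    adata.uns["carousel_config"] = {k: v for k, v in asdict(config).items()}
    if out_path is not None:
        adata.write_h5ad(Path(out_path))
    return adata
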