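"""Chunked, memory-frugal I/O for sparse cell-by-region matrices.

Large single-cell chromatin accessibility matrices (hundreds of thousands of
cells, a million peaks) do not fit comfortably in RAM.  This module reads
h5ad files in backed mode so that only the row slice currently being
processed is materialised, partitions the matrix into contiguous chunks of a
fixed number of cells, and re-assembles per-chunk metacell outputs into one
combined metacell-by-region matrix.

Chunks are consecutive slices in the input's existing row order; no
shuffling is performed.  Every chunk keeps the full (global) region axis —
region filtering is a per-chunk preprocessing step downstream and never
alters the stored raw counts, because metacell aggregation averages the raw
matrix over all regions.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp

__all__ = [
    "BackedMatrix",
    "ChunkSpec",
    "MetacellMatrix",
    "open_backed",
    "read_mtx_triplet",
    "partition_into_chunks",
    "load_chunk",
    "concatenate_metacells",
]

#: cells in a dense main matrix above which open_backed refuses to densify
DENSE_CAP_CELLS = 50_000

MEMBER_DELIMITER = ";"


@dataclass
class ChunkSpec:
    """One contiguous row interval of the parent matrix, serialized to disk.

    Intervals are 0-based and half-open: rows ``[start_row, end_row)``.
    """

    index: int
    start_row: int
    end_row: int
    path: Path

    @property
    def n_cells(self) -> int:
        return self.end_row - self.start_row


@dataclass
class MetacellMatrix:
    """Metacell-by-region matrix with per-metacell member identifier lists.

    ``values`` rows are arithmetic means of the member cells' raw count rows,
    hence real-valued even though the input counts are integers.
    """

    values: sp.csr_matrix
    region_ids: list[str]
    members: list[list[str]]
    chunk_of: list[int]

    @property
    def n_metacells(self) -> int:
        return self.values.shape[0]

    @property
    def sizes(self) -> np.ndarray:
        return np.array([len(m) for m in self.members], dtype=int)

    def to_anndata(self) -> ad.AnnData:
        """Pack into AnnData; membership goes into ``obs`` as delimited ids."""
        obs = pd.DataFrame(
            {
                "members": [MEMBER_DELIMITER.join(m) for m in self.members],
                "n_members": self.sizes,
                "chunk": np.asarray(self.chunk_of, dtype=int),
            },
            index=[f"metacell_{i}" for i in range(self.n_metacells)],
        )
        var = pd.DataFrame(index=pd.Index(self.region_ids, name="region"))
        return ad.AnnData(X=self.values.copy(), obs=obs, var=var)

    @classmethod
    def from_anndata(cls, adata: ad.AnnData) -> "MetacellMatrix":
        members = [str(m).split(MEMBER_DELIMITER) for m in adata.obs["members"]]
        return cls(
            values=sp.csr_matrix(adata.X),
            region_ids=list(adata.var_names),
            members=members,
            chunk_of=list(np.asarray(adata.obs["chunk"], dtype=int)),
        )


class BackedMatrix:
    """Handle over an on-disk sparse cell-by-region matrix.

    Exposes shape, identifiers and contiguous row-slice reads without ever
    materialising the full matrix.  The most recently read slice is cached,
    which speeds up the recurrent access pattern of sequential chunking; the
    contract is value-equality with an eager read, not any caching behaviour.
    """

    def __init__(self, adata: ad.AnnData, path: Path):
        self._adata = adata
        self.path = Path(path)
        self._cache: tuple[int, int, sp.csr_matrix] | None = None

    @property
    def shape(self) -> tuple[int, int]:
        return self._adata.shape

    @property
    def n_cells(self) -> int:
        return self._adata.shape[0]

    @property
    def n_regions(self) -> int:
        return self._adata.shape[1]

    @property
    def cell_ids(self) -> list[str]:
        return list(self._adata.obs_names)

    @property
    def region_ids(self) -> list[str]:
        return list(self._adata.var_names)

    @property
    def obs(self) -> pd.DataFrame:
        return self._adata.obs

    def rows(self, start: int, end: int) -> sp.csr_matrix:
        """Read rows ``[start, end)`` as an in-memory CSR integer matrix."""
        if not (0 <= start <= end <= self.n_cells):
            raise IndexError(f"row interval [{start}, {end}) out of bounds for {self.n_cells} cells")
        if self._cache is not None and self._cache[0] == start and self._cache[1] == end:
            return self._cache[2]
        X = self._adata.X[start:end]
        if hasattr(X, "to_memory"):  # backed sparse dataset
            X = X.to_memory()
        X = sp.csr_matrix(X)
        self._cache = (start, end, X)
        return X

    def close(self) -> None:
        if self._adata.isbacked and self._adata.file is not None:
            self._adata.file.close()

    def __enter__(self) -> "BackedMatrix":
        return self

    def __exit__(self, *exc) -> None:
        self.close()


def open_backed(path: str | os.PathLike) -> BackedMatrix:
    """Open an h5ad file lazily and return a :class:`BackedMatrix` handle.

    Raises
    ------
    FileNotFoundError
        if ``path`` does not exist.
    ValueError
        if the main matrix is dense and larger than ``DENSE_CAP_CELLS`` cells
        (the caller must convert to sparse rather than silently densify), or
        the container is malformed.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"file not found: {path}")
    try:
        adata = ad.read_h5ad(path, backed="r")
    except FileNotFoundError:
        raise
    except Exception as exc:  # malformed container
        raise ValueError(f"could not read h5ad container {path}: {exc}") from exc
    X = adata.X
    is_sparse = sp.issparse(X) or hasattr(X, "format")  # in-memory or backed sparse
    if not is_sparse and adata.shape[0] > DENSE_CAP_CELLS:
        adata.file.close()
        raise ValueError(
            f"{path} stores a dense main matrix with {adata.shape[0]} cells "
            f"(cap {DENSE_CAP_CELLS}); convert to CSR before processing"
        )
    return BackedMatrix(adata, path)


def read_mtx_triplet(
    mtx_path: str | os.PathLike,
    cells_path: str | os.PathLike,
    regions_path: str | os.PathLike,
    out_h5ad: str | os.PathLike,
) -> Path:
    """Convert a MatrixMarket matrix plus two identifier TSVs to h5ad.

    The MTX is expected cell-by-region; identifier files hold one id per line
    (first column if tab-separated).  Returns the written h5ad path.
    """
    from scipy.io import mmread

    X = sp.csr_matrix(mmread(os.fspath(mtx_path)))
    cells = pd.read_csv(cells_path, sep="\t", header=None)[0].astype(str).tolist()
    regions = pd.read_csv(regions_path, sep="\t", header=None)[0].astype(str).tolist()
    if X.shape != (len(cells), len(regions)):
        raise ValueError(
            f"matrix shape {X.shape} does not match {len(cells)} cells x {len(regions)} regions"
        )
    adata = ad.AnnData(
        X=X.astype(np.int64),
        obs=pd.DataFrame(index=pd.Index(cells, name="cell")),
        var=pd.DataFrame(index=pd.Index(regions, name="region")),
    )
    out_h5ad = Path(out_h5ad)
    adata.write_h5ad(out_h5ad)
    return out_h5ad


def partition_into_chunks(
    X: BackedMatrix,
    c: int,
    out_dir: str | os.PathLike,
    prefix: str = "carousel",
) -> list[ChunkSpec]:
    """Sequentially partition the matrix into ⌈n/c⌉ chunks of ``c`` cells.

    Each chunk is written as an independent h5ad file holding its raw count
    slice with cell and region identifiers, so chunks can be processed by
    separate worker processes.  The last chunk may be smaller than ``c``.
    """
    if c < 2:
        raise ValueError(f"chunk size c must be >= 2, got {c}")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    n = X.n_cells
    region_index = pd.Index(X.region_ids, name="region")
    cell_ids = X.cell_ids
    specs: list[ChunkSpec] = []
    for k, start in enumerate(range(0, n, c)):
        end = min(start + c, n)
        counts = X.rows(start, end)
        chunk = ad.AnnData(
            X=counts,
            obs=pd.DataFrame(index=pd.Index(cell_ids[start:end], name="cell")),
            var=pd.DataFrame(index=region_index),
        )
        path = out_dir / f"{prefix}_chunk{k}.h5ad"
        chunk.write_h5ad(path)
        specs.append(ChunkSpec(index=k, start_row=start, end_row=end, path=path))
    return specs


def load_chunk(spec: ChunkSpec) -> ad.AnnData:
    """Eagerly load one chunk file."""
    return ad.read_h5ad(spec.path)


def concatenate_metacells(chunk_outputs: Sequence[MetacellMatrix]) -> MetacellMatrix:
    """Row-stack per-chunk metacell matrices in chunk order.

    All inputs must share the same global region axis; member identifier
    lists are preserved verbatim and must be disjoint across metacells.
    """
    if not chunk_outputs:
        raise ValueError("no chunk outputs to concatenate")
    regions = chunk_outputs[0].region_ids
    for mc in chunk_outputs[1:]:
        if mc.region_ids != regions:
            raise ValueError("chunk outputs have mismatched region axes")
    members: list[list[str]] = []
    chunk_of: list[int] = []
    for mc in chunk_outputs:
        members.extend(mc.members)
        chunk_of.extend(mc.chunk_of)
    flat = [m for group in members for m in group]
    if len(flat) != len(set(flat)):
        raise ValueError("duplicate member identifiers across metacells")
    values = sp.vstack([mc.values for mc in chunk_outputs], format="csr")
    return MetacellMatrix(values=values, region_ids=list(regions), members=members, chunk_of=chunk_of)
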