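"""Per-chunk preprocessing: from raw counts to a weighted cell-cell graph.

Single-cell chromatin accessibility counts are near-binary and extremely
sparse, so the standard LSI-style recipe is used per chunk:

1. binarize the counts (any positive count becomes 1);
2. drop regions accessible in too few cells of the chunk (strictly more
   than ``frac * c`` cells required, default frac = 0.01);
3. TF-IDF re-weighting of the binary matrix;
4. PCA to 50 components;
5. exact Euclidean k-nearest-neighbour graph with locally-scaled Gaussian
   connectivity weights, symmetrized.

No cell is ever dropped: a cell whose filtered row is all zeros simply
embeds at the centred origin and stays in the graph.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors

__all__ = [
    "BinaryMatrix",
    "NeighborGraph",
    "binarize",
    "filter_regions_chunk",
    "tfidf_transform",
    "pca_embed",
    "build_neighbor_graph",
]


@dataclass
class BinaryMatrix:
    """Sparse 0/1 matrix over a retained subset of the global region axis."""

    values: sp.csr_matrix
    kept_region_idx: np.ndarray

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass
class NeighborGraph:
    """Symmetric weighted kNN adjacency with weights in (0, 1]."""

    weights: sp.csr_matrix
    k: int

    @property
    def n_cells(self) -> int:
        return self.weights.shape[0]


def binarize(X: sp.spmatrix | np.ndarray) -> BinaryMatrix:
    """Set every positive entry to 1.  Idempotent; rejects negative counts."""
    X = sp.csr_matrix(X)
    if X.nnz and X.data.min() < 0:
        raise ValueError("count matrix has negative entries")
    B = X.copy()
    B.data = np.ones_like(B.data, dtype=np.int8)
    B.eliminate_zeros()
    return BinaryMatrix(values=B, kept_region_idx=np.arange(X.shape[1]))


def filter_regions_chunk(B: BinaryMatrix, c: int | None = None, frac: float = 0.01) -> BinaryMatrix:
    """Keep regions accessible in strictly more than ``frac * c`` cells.

    ``c`` defaults to the chunk's cell count.  The inequality is strict: with
    c=1000 a region open in exactly 10 cells is dropped, one open in 11 is
    kept.  An empty result is legal; downstream steps must cope with zero
    retained regions.
    """
    if not (0.0 < frac < 1.0):
        raise ValueError(f"frac must lie in (0, 1), got {frac}")
    if c is None:
        c = B.values.shape[0]
    col_sums = np.asarray(B.values.sum(axis=0)).ravel()
    keep = col_sums > frac * c
    return BinaryMatrix(
        values=B.values[:, keep].tocsr(),
        kept_region_idx=B.kept_region_idx[keep],
    )


def tfidf_transform(B: BinaryMatrix) -> sp.csr_matrix:
    """TF-IDF re-weighting of a binary accessibility matrix.

    TF[i, j] = B[i, j] / (row sum of i); IDF[j] = ln(1 + n / df_j) with
    df_j the number of cells in which region j is open.  Rows with zero sum
    map to all-zero rows.  Columns with df = 0 (possible only on unfiltered
    input) get IDF 0 — the column is all-zero anyway.
    """
    n, p = B.values.shape
    if p == 0:
        raise ValueError("TF-IDF on zero retained regions")
    V = B.values.astype(np.float64)
    row_sums = np.asarray(V.sum(axis=1)).ravel()
    inv_rows = np.divide(1.0, row_sums, out=np.zeros_like(row_sums), where=row_sums > 0)
    tf = sp.diags(inv_rows) @ V
    df = np.asarray(B.values.sum(axis=0)).ravel().astype(np.float64)
    idf = np.where(df > 0, np.log1p(np.divide(n, df, out=np.zeros_like(df), where=df > 0)), 0.0)
    out = (tf @ sp.diags(idf)).tocsr()
    out.eliminate_zeros()
    return out


def pca_embed(T: sp.spmatrix | np.ndarray, n_components: int = 50, seed: int = 0) -> np.ndarray:
    """Column-mean-centred principal component scores.

    The number of components returned is ``min(n_components, cells - 1,
    regions)``.  Components are ordered by decreasing explained variance and
    the decomposition is deterministic for a fixed seed.
    """
    if sp.issparse(T):
        T = np.asarray(T.todense())
    T = np.asarray(T, dtype=np.float64)
    n, p = T.shape
    if n < 2:
        raise ValueError("PCA needs at least 2 cells")
    if not np.all(np.isfinite(T)):
        raise ValueError("non-finite entries in PCA input")
    k = min(n_components, n - 1, p)
    pca = PCA(n_components=k, svd_solver="auto", random_state=seed)
    return pca.fit_transform(T)


def build_neighbor_graph(E: np.ndarray, k: int = 15, seed: int = 0) -> NeighborGraph:
    """Exact Euclidean kNN graph with locally-scaled Gaussian connectivities.

    For each directed kNN edge i→j the weight is

        w_ij = exp(-(d_ij^2 - rho_i * rho_j) / (sigma_i * sigma_j))

    with rho_i the distance from i to its nearest neighbour and sigma_i the
    distance to its k-th neighbour (self excluded).  Because rho_i <= d_ij
    and rho_j <= d_ij for any kNN edge, weights lie in (0, 1]; the nearest
    mutual pair gets weight exactly 1.  The graph is symmetrized by
    elementwise maximum and has a zero diagonal.

    ``seed`` is accepted for interface uniformity; the exact search is
    deterministic.
    """
    E = np.asarray(E, dtype=np.float64)
    n = E.shape[0]
    if n < 2:
        raise ValueError("need at least 2 cells to build a graph")
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    if k >= n:
        raise ValueError(f"k={k} must be smaller than the number of cells ({n})")

    nn = NearestNeighbors(n_neighbors=k + 1, algorithm="auto", metric="euclidean")
    nn.fit(E)
    dist, idx = nn.kneighbors(E)

    # drop the self hit; with duplicate points self may not be first, so
    # remove by index match (exactly one per row) and keep k neighbours
    rows_src = np.empty((n, k), dtype=np.int64)
    rows_dst = np.empty((n, k), dtype=np.int64)
    rows_d = np.empty((n, k), dtype=np.float64)
    for i in range(n):
        mask = idx[i] != i
        if mask.sum() == k + 1:  # self absent among ties: drop farthest
            mask[np.argmax(dist[i])] = False
        rows_dst[i] = idx[i][mask][:k]
        rows_d[i] = dist[i][mask][:k]
        rows_src[i] = i

    rho = rows_d[:, 0]  # nearest-neighbour distance per cell
    sigma = rows_d[:, -1]  # k-th-neighbour distance per cell

    src = rows_src.ravel()
    dst = rows_dst.ravel()
    d = rows_d.ravel()
    denom = sigma[src] * sigma[dst]
    num = d**2 - rho[src] * rho[dst]
    with np.errstate(divide="ignore", invalid="ignore"):
        w = np.where(denom > 0, np.exp(-np.where(denom > 0, num / np.maximum(denom, 1e-300), 0.0)), 1.0)
    w = np.clip(w, 0.0, 1.0)
    w = np.maximum(w, 1e-300)  # keep every kNN edge strictly positive

    W = sp.coo_matrix((w, (src, dst)), shape=(n, n)).tocsr()
    W = W.maximum(W.T)
    W.setdiag(0)
    W.eliminate_zeros()
    return NeighborGraph(weights=W.tocsr(), k=k)
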