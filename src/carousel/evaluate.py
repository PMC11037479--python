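"""Downstream evaluation of metacells via cell clustering agreement.

The protocol mirrors how metacell quality is judged in practice: the
metacell-by-region matrix is binarized (any positive mean, e.g. 0.2, counts
as accessible), features are selected with a sparsity-adjusted threshold,
the same TF-IDF → PCA → kNN recipe used upstream produces a metacell graph,
and Louvain/Leiden community detection clusters the metacells.  Each cell
then inherits its metacell's cluster label, and the propagated labels are
scored against ground-truth cell types with six standard agreement metrics.

Four clustering strategies are supported:

- ``Dlouvain`` / ``Dleiden`` — Louvain / Leiden at the default resolution 1.0;
- ``Clouvain`` / ``Cleiden`` — resolution binary-searched so that the number
  of clusters matches the known number of cell types.

Feature selection threshold: with s_o the sparsity (non-zero proportion) of
the raw matrix and s_mc that of the metacell matrix, regions accessible in
strictly more than 0.01 × s_mc / s_o of the metacells are retained.
Aggregation densifies the matrix (s_mc > s_o), so the threshold scales up
accordingly.
"""

from __future__ import annotations

import logging
import random
from collections import Counter
from dataclasses import dataclass, field

import igraph
import leidenalg
import numpy as np
import scipy.sparse as sp
from sklearn import metrics as skm

from .io import MetacellMatrix
from .preprocess import BinaryMatrix, build_neighbor_graph, pca_embed, tfidf_transform

__all__ = [
    "STRATEGIES",
    "SparsityStats",
    "EvaluationReport",
    "metacell_binarize",
    "compute_sparsity",
    "select_metacell_features",
    "cluster_metacells",
    "binary_search_resolution",
    "propagate_labels",
    "score_clustering",
    "metacell_purity",
    "evaluate_metacells",
]

logger = logging.getLogger("carousel")

STRATEGIES = ("Dlouvain", "Dleiden", "Clouvain", "Cleiden")
METRIC_NAMES = ("AMI", "ARI", "NMI", "Homo", "completeness", "FMI")


@dataclass
class SparsityStats:
    """Non-zero proportions of the raw (s_o) and metacell (s_mc) matrices."""

    s_o: float
    s_mc: float


@dataclass
class EvaluationReport:
    """Per-strategy propagated cell labels, metric values and search traces."""

    labels: dict[str, np.ndarray] = field(default_factory=dict)
    scores: dict[str, dict[str, float]] = field(default_factory=dict)
    resolutions: dict[str, float] = field(default_factory=dict)
    search_traces: dict[str, list[tuple[float, int]]] = field(default_factory=dict)
    purity: np.ndarray | None = None

    def to_dict(self) -> dict:
        out = {
            "scores": self.scores,
            "resolutions": self.resolutions,
            "search_traces": {k: [[r, c] for r, c in v] for k, v in self.search_traces.items()},
        }
        if self.purity is not None:
            out["purity"] = {
                "mean": float(self.purity.mean()),
                "min": float(self.purity.min()),
                "median": float(np.median(self.purity)),
            }
        return out


def metacell_binarize(M: MetacellMatrix | sp.spmatrix | np.ndarray) -> BinaryMatrix:
    """Binarize a metacell matrix: any positive mean (0.2 included) becomes 1."""
    X = M.values if isinstance(M, MetacellMatrix) else M
    X = sp.csr_matrix(X)
    if X.nnz and X.data.min() < 0:
        raise ValueError("metacell matrix has negative values")
    B = X.copy()
    B.data = np.ones_like(B.data, dtype=np.int8)
    B.eliminate_zeros()
    return BinaryMatrix(values=B, kept_region_idx=np.arange(X.shape[1]))


def compute_sparsity(X: sp.spmatrix | np.ndarray) -> float:
    """Proportion of non-zero entries."""
    if sp.issparse(X):
        total = X.shape[0] * X.shape[1]
        nnz = X.nnz
    else:
        X = np.asarray(X)
        total = X.size
        nnz = int(np.count_nonzero(X))
    if total == 0:
        raise ValueError("empty matrix")
    return nnz / total


def select_metacell_features(Bmc: BinaryMatrix, s_o: float, s_mc: float) -> BinaryMatrix:
    """Keep regions open in strictly more than 0.01 × s_mc/s_o of metacells."""
    if s_o <= 0:
        raise ValueError("raw sparsity s_o must be positive")
    n_mc = Bmc.values.shape[0]
    frac_open = np.asarray(Bmc.values.sum(axis=0)).ravel() / n_mc
    threshold = 0.01 * s_mc / s_o
    keep = frac_open > threshold
    return BinaryMatrix(values=Bmc.values[:, keep].tocsr(), kept_region_idx=Bmc.kept_region_idx[keep])


def _graph_from_weights(W: sp.csr_matrix) -> igraph.Graph:
    coo = sp.triu(W, k=1).tocoo()
    g = igraph.Graph(
        n=W.shape[0],
        edges=list(zip(coo.row.tolist(), coo.col.tolist())),
        edge_attrs={"weight": coo.data.tolist()},
    )
    return g


def _cluster_graph(g: igraph.Graph, method: str, resolution: float, seed: int) -> np.ndarray:
    if method == "leiden":
        part = leidenalg.find_partition(
            g,
            leidenalg.RBConfigurationVertexPartition,
            weights="weight",
            resolution_parameter=resolution,
            seed=seed,
            n_iterations=2,
        )
        return np.asarray(part.membership)
    if method == "louvain":
        random.seed(seed)  # igraph's default RNG hooks Python's random module
        part = g.community_multilevel(weights="weight", resolution=resolution)
        return np.asarray(part.membership)
    raise ValueError(f"unknown clustering method {method!r}")


def binary_search_resolution(
    cluster_fn,
    target_k: int,
    lo: float = 1e-3,
    hi: float = 10.0,
    max_iter: int = 50,
) -> tuple[float, list[tuple[float, int]]]:
    """Bisect the resolution so the cluster count matches ``target_k``.

    ``cluster_fn`` maps a resolution to a cluster count and is assumed
    weakly increasing.  Returns the matching resolution, or after
    ``max_iter`` halvings the probed resolution whose count is closest to
    ``target_k`` (ties → lower resolution), together with the search trace.
    """
    if target_k < 1:
        raise ValueError("target_k must be >= 1")
    trace: list[tuple[float, int]] = []

    def probe(res: float) -> int:
        k = int(cluster_fn(res))
        trace.append((res, k))
        return k

    for bound in (lo, hi):
        if probe(bound) == target_k:
            return bound, trace
    if trace[0][1] > target_k or trace[1][1] < target_k:
        logger.warning(
            "target cluster count %d outside [%d, %d] reachable on (%g, %g)",
            target_k, trace[0][1], trace[1][1], lo, hi,
        )
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        k = probe(mid)
        if k == target_k:
            return mid, trace
        if k < target_k:
            lo = mid
        else:
            hi = mid
    best = min(trace, key=lambda rc: (abs(rc[1] - target_k), rc[0]))
    logger.warning("binary search exhausted; closest count %d at resolution %g", best[1], best[0])
    return best[0], trace


def cluster_metacells(
    Bmc: BinaryMatrix,
    strategy: str,
    target_k: int | None = None,
    seed: int = 0,
    k_neighbors: int = 15,
    n_components: int = 50,
) -> tuple[np.ndarray, float, list[tuple[float, int]]]:
    """Cluster metacells with one of the four strategies.

    Returns (labels, resolution used, binary-search trace).  The D-variants
    use resolution 1.0; the C-variants require ``target_k`` (the true number
    of cell types) and binary-search the resolution to match it.
    """
    if strategy not in STRATEGIES:
        raise ValueError(f"strategy must be one of {STRATEGIES}, got {strategy!r}")
    method = "louvain" if "louvain" in strategy else "leiden"
    adaptive = strategy.startswith("C")
    if adaptive and target_k is None:
        raise ValueError(f"{strategy} requires target_k (the true number of cell types)")

    # With K metacells, retaining close to K components defeats PCA's
    # denoising (pairwise distances approach the full-rank ones and the
    # binarization noise floor drowns the type signal), so cap the number of
    # components requested at half the sample count.
    n_mc = Bmc.values.shape[0]
    n_comp = min(n_components, max(2, (n_mc - 1) // 2))
    T = tfidf_transform(Bmc)
    E = pca_embed(T, n_components=n_comp, seed=seed)
    k = min(k_neighbors, E.shape[0] - 1)
    graph = build_neighbor_graph(E, k=k, seed=seed)
    g = _graph_from_weights(graph.weights)

    if not adaptive:
        return _cluster_graph(g, method, 1.0, seed), 1.0, []

    def count_at(res: float) -> int:
        return len(np.unique(_cluster_graph(g, method, res, seed)))

    res, trace = binary_search_resolution(count_at, target_k)
    return _cluster_graph(g, method, res, seed), res, trace


def propagate_labels(
    metacell_labels: np.ndarray,
    members: list[list[str]],
    cell_ids: list[str],
) -> np.ndarray:
    """Assign each cell the cluster label of its metacell."""
    lut: dict[str, object] = {}
    for lab, group in zip(metacell_labels, members):
        for m in group:
            lut[m] = lab
    try:
        return np.asarray([lut[c] for c in cell_ids])
    except KeyError as exc:
        raise ValueError(f"cell missing from all membership lists: {exc}") from exc


def score_clustering(pred: np.ndarray, truth: np.ndarray) -> dict[str, float]:
    """Six agreement metrics between predicted and true cell labels.

    AMI and NMI use arithmetic-mean normalization; ARI follows
    Hubert–Arabie; Homo/completeness are the entropy-based scores; FMI is
    the geometric mean of pairwise precision and recall.
    """
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape != truth.shape:
        raise ValueError(f"label vectors differ in length: {pred.shape} vs {truth.shape}")
    return {
        "AMI": float(skm.adjusted_mutual_info_score(truth, pred, average_method="arithmetic")),
        "ARI": float(skm.adjusted_rand_score(truth, pred)),
        "NMI": float(skm.normalized_mutual_info_score(truth, pred, average_method="arithmetic")),
        "Homo": float(skm.homogeneity_score(truth, pred)),
        "completeness": float(skm.completeness_score(truth, pred)),
        "FMI": float(skm.fowlkes_mallows_score(truth, pred)),
    }


def metacell_purity(members: list[list[str]], labels: dict[str, str]) -> np.ndarray:
    """Fraction of each metacell's members sharing its dominant cell type."""
    out = np.empty(len(members))
    for i, group in enumerate(members):
        if not group:
            raise ValueError("empty metacell")
        counts = Counter(labels[m] for m in group)
        out[i] = max(counts.values()) / len(group)
    return out


def evaluate_metacells(
    mc: MetacellMatrix,
    truth: dict[str, str],
    raw_sparsity: float,
    strategies: tuple[str, ...] = STRATEGIES,
    seed: int = 0,
) -> EvaluationReport:
    """Run the full evaluation protocol for the requested strategies.

    ``truth`` maps cell id → true type; ``raw_sparsity`` is s_o of the raw
    matrix (computed before aggregation, since the evaluation never needs to
    reload the raw data).
    """
    cell_ids = [m for group in mc.members for m in group]
    truth_vec = np.asarray([truth[c] for c in cell_ids])
    n_types = len(set(truth.values()))

    s_mc = compute_sparsity(mc.values)
    stats = SparsityStats(s_o=raw_sparsity, s_mc=s_mc)
    Bmc = metacell_binarize(mc)
    Bsel = select_metacell_features(Bmc, stats.s_o, stats.s_mc)
    logger.info(
        "evaluation: %d metacells, %d/%d regions kept (threshold %.4f)",
        mc.n_metacells, Bsel.shape[1], Bmc.shape[1], 0.01 * stats.s_mc / stats.s_o,
    )

    report = EvaluationReport()
    report.purity = metacell_purity(mc.members, truth)
    for strat in strategies:
        target = n_types if strat.startswith("C") else None
        mc_labels, res, trace = cluster_metacells(Bsel, strat, target_k=target, seed=seed)
        cell_labels = propagate_labels(mc_labels, mc.members, cell_ids)
        report.labels[strat] = cell_labels
        report.scores[strat] = score_clustering(cell_labels, truth_vec)
        report.resolutions[strat] = res
        report.search_traces[strat] = trace
    return report
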