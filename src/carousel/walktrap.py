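"""Weighted Walktrap community detection cut at a requested community count.

The method embeds each vertex ``a`` of a weighted graph as the probability
row of a length-``l`` random walk started at ``a``.  With U the symmetric
weighted adjacency, degrees d_a = sum_b U_ab and transition matrix
P = V^{-1} U (V = diag(d)), the distance between vertices a and b is

    r_ab = sqrt( sum_k (P^l_ak - P^l_bk)^2 / d_k )
         = || V^{-1/2} P^l_a. - V^{-1/2} P^l_b. ||_2 ,

and the distance between communities uses the member-averaged walk row
P^l_{Y.} = mean_{a in Y} P^l_{a.}.  Starting from singletons, the pair of
*adjacent* communities minimising the Ward-style merge cost

    Delta_sigma(Y1, Y2) = (1/c) [ sum_{a in Y3} r^2_{a,Y3}
                                  - sum_{a in Y1} r^2_{a,Y1}
                                  - sum_{a in Y2} r^2_{a,Y2} ],   Y3 = Y1 u Y2,

is merged at every step until the requested number of communities remains.
Because the vertex embeddings are plain Euclidean points (phi_a =
V^{-1/2} P^l_{a.}), the merge cost has the closed Ward form

    Delta_sigma(Y1, Y2) = (1/c) * |Y1||Y2| / (|Y1|+|Y2|) * r^2_{Y1 Y2},

which the optimized merge loop uses; it is contractually equal to the
definitional sum above (exercised by the test-suite oracle).

Ties within 1e-12 of the minimum merge cost are broken by the
lexicographically smallest pair of community representatives, each
community being represented by its minimum member index — this makes the
merge sequence deterministic.

Disconnected graphs are handled by running the merge loop per connected
component, splitting the community budget across components proportionally
to their sizes (largest-remainder rounding, every component gets at least
one community).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components

from .preprocess import NeighborGraph

__all__ = [
    "TransitionModel",
    "CommunityPartition",
    "transition_matrix",
    "walk_probabilities",
    "cell_distance",
    "community_distance",
    "merge_cost",
    "walktrap_partition",
    "allocate_budget",
]

TIE_TOL = 1e-12


@dataclass
class TransitionModel:
    """Row-stochastic random-walk model P = V^{-1} U with walk length l."""

    P: sp.csr_matrix
    d: np.ndarray
    l: int = 4

    @property
    def n(self) -> int:
        return self.P.shape[0]


@dataclass
class CommunityPartition:
    """Disjoint cover of the vertices plus the ordered merge history.

    ``assignment[v]`` is the community id of vertex v; ids are 0..K-1,
    ordered by each community's minimum member index.  ``merge_history``
    records (rep1, rep2, delta_sigma) for every merge performed, in order.
    """

    assignment: np.ndarray
    merge_history: list[tuple[int, int, float]] = field(default_factory=list)

    @property
    def n_communities(self) -> int:
        return int(self.assignment.max()) + 1 if self.assignment.size else 0

    def members(self) -> list[np.ndarray]:
        return [np.flatnonzero(self.assignment == k) for k in range(self.n_communities)]


def _as_csr(U) -> sp.csr_matrix:
    if isinstance(U, NeighborGraph):
        U = U.weights
    return sp.csr_matrix(U, dtype=np.float64)


def transition_matrix(U, l: int = 4) -> TransitionModel:
    """Row-normalise the weighted adjacency into transition probabilities."""
    U = _as_csr(U)
    if (abs(U - U.T) > 1e-12 * max(1.0, abs(U).max())).nnz:
        raise ValueError("adjacency must be symmetric")
    if U.nnz and U.data.min() < 0:
        raise ValueError("adjacency weights must be non-negative")
    d = np.asarray(U.sum(axis=1)).ravel()
    if np.any(d <= 0):
        raise ValueError("zero-degree vertex: attach isolated vertices before building P")
    P = sp.diags(1.0 / d) @ U
    return TransitionModel(P=P.tocsr(), d=d, l=l)


def walk_probabilities(M: TransitionModel) -> np.ndarray:
    """Dense P^l: the l-step walk probability matrix (rows sum to 1)."""
    return np.linalg.matrix_power(M.P.toarray(), M.l)


def _phi(M: TransitionModel, Pl: np.ndarray | None = None) -> np.ndarray:
    """Vertex embeddings phi_a = V^{-1/2} P^l_{a.} (rows)."""
    if Pl is None:
        Pl = walk_probabilities(M)
    return Pl / np.sqrt(M.d)[None, :]


def cell_distance(M: TransitionModel, a: int, b: int, Pl: np.ndarray | None = None) -> float:
    """Walk distance r_ab between two vertices."""
    phi = _phi(M, Pl)
    return float(np.linalg.norm(phi[a] - phi[b]))


def community_distance(
    M: TransitionModel,
    Y1: Sequence[int],
    Y2: Sequence[int],
    Pl: np.ndarray | None = None,
) -> float:
    """Walk distance r_{Y1 Y2} between two (non-empty) vertex sets."""
    Y1 = np.asarray(list(Y1), dtype=int)
    Y2 = np.asarray(list(Y2), dtype=int)
    if Y1.size == 0 or Y2.size == 0:
        raise ValueError("communities must be non-empty")
    phi = _phi(M, Pl)
    return float(np.linalg.norm(phi[Y1].mean(axis=0) - phi[Y2].mean(axis=0)))


def merge_cost(
    M: TransitionModel,
    Y1: Sequence[int],
    Y2: Sequence[int],
    c: int | None = None,
    Pl: np.ndarray | None = None,
) -> float:
    """Definitional merge cost Delta_sigma(Y1, Y2).

    Evaluates the within-community squared-distance sums of Y1, Y2 and
    Y3 = Y1 u Y2 directly; any optimised update formula must agree with
    this evaluation.  ``c`` defaults to the number of vertices.
    """
    Y1 = np.asarray(list(Y1), dtype=int)
    Y2 = np.asarray(list(Y2), dtype=int)
    if np.intersect1d(Y1, Y2).size:
        raise ValueError("communities overlap")
    if c is None:
        c = M.n
    phi = _phi(M, Pl)

    def within(Y: np.ndarray) -> float:
        centroid = phi[Y].mean(axis=0)
        return float(((phi[Y] - centroid) ** 2).sum())

    Y3 = np.concatenate([Y1, Y2])
    return (within(Y3) - within(Y1) - within(Y2)) / c


def allocate_budget(sizes: Sequence[int], target_k: int) -> list[int]:
    """Split ``target_k`` communities across components by largest remainder.

    Every component receives at least 1 and at most its size; the quotas are
    proportional to component sizes.  Deterministic: remainder ties go to the
    smaller component index.
    """
    sizes = list(sizes)
    n = sum(sizes)
    m = len(sizes)
    if target_k < m:
        raise ValueError(
            f"target_k={target_k} is below the number of connected components ({m}); "
            "communities cannot span components"
        )
    if target_k > n:
        raise ValueError(f"target_k={target_k} exceeds the number of vertices ({n})")
    quota = [target_k * s / n for s in sizes]
    alloc = [min(max(int(np.floor(q)), 1), s) for q, s in zip(quota, sizes)]
    # distribute the remaining budget by largest fractional remainder
    order = sorted(range(m), key=lambda i: (-(quota[i] - np.floor(quota[i])), i))
    deficit = target_k - sum(alloc)
    j = 0
    while deficit > 0:
        i = order[j % m]
        if alloc[i] < sizes[i]:
            alloc[i] += 1
            deficit -= 1
        j += 1
    while deficit < 0:
        i = order[(j := j + 1) % m]
        if alloc[i] > 1:
            alloc[i] -= 1
            deficit += 1
    return alloc


def _merge_component(
    Usub: sp.csr_matrix,
    nodes: np.ndarray,
    target_k: int,
    l: int,
    c_norm: int,
    history: list[tuple[int, int, float]],
) -> dict[int, list[int]]:
    """Run the agglomerative loop on one connected component.

    ``nodes`` maps local vertex indices to global ones; ``c_norm`` is the
    global cell count used in the 1/c factor of the merge cost.  Returns a
    map from community representative (global min member index) to the list
    of global member indices.
    """
    n = Usub.shape[0]
    M = transition_matrix(Usub, l=l)
    phi = _phi(M)

    # community state keyed by representative = min global member index
    comm_sum = {int(nodes[i]): phi[i].copy() for i in range(n)}
    comm_size = {int(nodes[i]): 1 for i in range(n)}
    comm_members = {int(nodes[i]): [int(nodes[i])] for i in range(n)}
    local_of = {int(nodes[i]): i for i in range(n)}

    adj: dict[int, set[int]] = {int(nodes[i]): set() for i in range(n)}
    coo = sp.triu(Usub, k=1).tocoo()
    for i, j in zip(coo.row, coo.col):
        a, b = int(nodes[i]), int(nodes[j])
        adj[a].add(b)
        adj[b].add(a)

    def ward(r1: int, r2: int) -> float:
        s1, s2 = comm_size[r1], comm_size[r2]
        mu1 = comm_sum[r1] / s1
        mu2 = comm_sum[r2] / s2
        r2dist = float(((mu1 - mu2) ** 2).sum())
        return (s1 * s2 / (s1 + s2)) * r2dist / c_norm

    pairs: dict[tuple[int, int], float] = {}
    for a, nbrs in adj.items():
        for b in nbrs:
            if a < b:
                pairs[(a, b)] = ward(a, b)

    n_comm = n
    while n_comm > target_k:
        if not pairs:
            raise RuntimeError("no adjacent pairs left before reaching target_k")
        mn = min(pairs.values())
        key = min(k for k, v in pairs.items() if v <= mn + TIE_TOL)
        r1, r2 = key
        dsig = pairs[key]
        history.append((r1, r2, dsig))

        # merge r2 into r1 (r1 < r2, so r1 stays the min-member representative)
        comm_sum[r1] += comm_sum[r2]
        comm_size[r1] += comm_size[r2]
        comm_members[r1].extend(comm_members[r2])
        del comm_sum[r2], comm_size[r2], comm_members[r2]

        new_nbrs = (adj[r1] | adj[r2]) - {r1, r2}
        for x in adj[r1]:
            pairs.pop((min(r1, x), max(r1, x)), None)
        for x in adj[r2]:
            pairs.pop((min(r2, x), max(r2, x)), None)
            adj[x].discard(r2)
        for x in new_nbrs:
            adj[x].discard(r1)
            adj[x].add(r1)
        del adj[r2]
        adj[r1] = new_nbrs
        for x in new_nbrs:
            pairs[(min(r1, x), max(r1, x))] = ward(r1, x)
        n_comm -= 1

    return comm_members


def walktrap_partition(U, target_k: int, l: int = 4) -> CommunityPartition:
    """Agglomerate singleton communities down to exactly ``target_k``.

    Only edge-connected pairs are merge candidates; the graph may be
    disconnected, in which case the budget is split across components
    (see :func:`allocate_budget`).
    """
    U = _as_csr(U)
    n = U.shape[0]
    if target_k < 1 or target_k > n:
        raise ValueError(f"target_k must be in [1, {n}], got {target_k}")

    n_comp, labels = connected_components(U, directed=False)
    sizes = [int((labels == i).sum()) for i in range(n_comp)]
    alloc = allocate_budget(sizes, target_k)

    history: list[tuple[int, int, float]] = []
    rep_members: dict[int, list[int]] = {}
    for comp in range(n_comp):
        nodes = np.flatnonzero(labels == comp)
        if alloc[comp] == len(nodes):
            for v in nodes:
                rep_members[int(v)] = [int(v)]
            continue
        Usub = U[np.ix_(nodes, nodes)].tocsr()
        rep_members.update(_merge_component(Usub, nodes, alloc[comp], l, n, history))

    assignment = np.empty(n, dtype=int)
    for cid, rep in enumerate(sorted(rep_members)):
        assignment[rep_members[rep]] = cid
    return CommunityPartition(assignment=assignment, merge_history=history)
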