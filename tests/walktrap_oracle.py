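"""Brute-force Walktrap oracle, independent of the package implementation.

Everything here is recomputed from the definitional formulas at every merge
step with plain numpy: the l-step walk matrix by explicit matrix power, the
community walk row as the plain mean of member rows, the walk distance as
the degree-weighted squared-difference sum, and the merge cost as the
difference of within-community squared-distance sums.  Deliberately O(n^4)
per run — usable only on tiny graphs.
"""

from __future__ import annotations

import numpy as np

TIE_TOL = 1e-12


def random_connected_graph(rng: np.random.Generator, n_max: int = 12) -> np.ndarray:
    """Random connected weighted undirected graph, weights in (0, 1]."""
    n = int(rng.integers(3, n_max + 1))
    U = np.zeros((n, n))
    order = rng.permutation(n)
    for i in range(1, n):  # random spanning tree keeps it connected
        a, b = order[i], order[int(rng.integers(0, i))]
        U[a, b] = U[b, a] = 1.0 - rng.random()
    extra = int(rng.integers(0, n))
    for _ in range(extra):
        a, b = rng.integers(0, n, size=2)
        if a != b:
            U[a, b] = U[b, a] = 1.0 - rng.random()
    return U


def brute_walktrap(U: np.ndarray, target_k: int, l: int = 4, c: int | None = None):
    """Full definitional Walktrap merge sequence down to ``target_k``.

    Returns (merge_history, communities) where merge_history is a list of
    (rep1, rep2, delta_sigma) and communities maps representative (min
    member) -> sorted member list.  Assumes the graph is connected.
    """
    U = np.asarray(U, dtype=float)
    n = U.shape[0]
    if c is None:
        c = n
    d = U.sum(axis=1)
    assert np.all(d > 0), "oracle needs a connected graph"
    P = U / d[:, None]
    Pl = np.linalg.matrix_power(P, l)

    def comm_row(Y):
        return Pl[list(Y)].mean(axis=0)

    def dist2(Y1, Y2):
        diff = comm_row(Y1) - comm_row(Y2)
        return float((diff**2 / d).sum())

    def within_sum(Y):
        return sum(dist2([a], Y) for a in Y)

    comms: dict[int, list[int]] = {i: [i] for i in range(n)}
    adjacent = lambda Y1, Y2: bool(U[np.ix_(Y1, Y2)].sum() > 0)
    history: list[tuple[int, int, float]] = []

    while len(comms) > target_k:
        costs: dict[tuple[int, int], float] = {}
        for r1 in sorted(comms):
            for r2 in sorted(comms):
                if r2 <= r1 or not adjacent(comms[r1], comms[r2]):
                    continue
                Y3 = comms[r1] + comms[r2]
                costs[(r1, r2)] = (
                    within_sum(Y3) - within_sum(comms[r1]) - within_sum(comms[r2])
                ) / c
        assert costs, "graph disconnected before reaching target_k"
        mn = min(costs.values())
        r1, r2 = min(k for k, v in costs.items() if v <= mn + TIE_TOL)
        history.append((r1, r2, costs[(r1, r2)]))
        comms[r1] = sorted(comms[r1] + comms[r2])
        del comms[r2]
    return history, comms
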