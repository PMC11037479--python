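"""Synthetic single-cell chromatin accessibility data with known structure.

The generator emulates the defining features of scCAS count matrices —
near-binary values, extreme sparsity, block-structured cell types — with a
simple Bernoulli block model: each cell draws a type, each type owns a
disjoint block of marker regions that are open with probability
``p_marker`` in matching cells, and every other entry is open with the
background probability ``p_background``.  An optional dropout step zeroes a
uniformly random fraction of the non-zero entries, emulating the loss of
observed accessibility events at increasing noise levels, and an optional
Poisson lift turns 0/1 values into small counts (1 + Poisson(0.2)) so the
binarization path is exercised.

The default desk-scale fixture is 3000 cells × 5000 regions, 5 equally
frequent types with 200 markers each, p_marker = 0.25, p_background = 0.01.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp

__all__ = ["FixtureSpec", "generate_sccas", "imbalance_profile", "write_fixture"]


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of the Bernoulli block model."""

    n_cells: int = 3000
    n_regions: int = 5000
    n_types: int = 5
    type_proportions: tuple[float, ...] | None = None
    markers_per_type: int = 200
    p_marker: float = 0.25
    p_background: float = 0.01
    dropout: float = 0.0
    poisson_lift: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_types > self.n_cells:
            raise ValueError("more cell types than cells")
        if not (0.0 <= self.p_background < self.p_marker <= 1.0):
            raise ValueError("need 0 <= p_background < p_marker <= 1")
        if not (0.0 <= self.dropout < 1.0):
            raise ValueError("dropout must lie in [0, 1)")
        if self.markers_per_type * self.n_types > self.n_regions:
            raise ValueError("marker blocks exceed the region axis")
        if self.type_proportions is not None:
            props = np.asarray(self.type_proportions)
            if len(props) != self.n_types or not np.isclose(props.sum(), 1.0):
                raise ValueError("type_proportions must be a length-n_types simplex vector")

    @property
    def proportions(self) -> np.ndarray:
        if self.type_proportions is None:
            return np.full(self.n_types, 1.0 / self.n_types)
        return np.asarray(self.type_proportions, dtype=float)


def generate_sccas(spec: FixtureSpec) -> tuple[ad.AnnData, np.ndarray]:
    """Draw one synthetic cell-by-region count matrix plus true type labels.

    Type ``t`` owns the marker block of columns
    ``[t*markers_per_type, (t+1)*markers_per_type)``.  Dropout zeroes exactly
    ``floor(dropout * nnz)`` uniformly chosen non-zero entries, so it never
    creates non-zeros.  Fully reproducible for a fixed seed.
    """
    rng = np.random.default_rng(spec.seed)
    n, p, mpt = spec.n_cells, spec.n_regions, spec.markers_per_type
    types = rng.choice(spec.n_types, size=n, p=spec.proportions)

    probs = np.full((n, p), spec.p_background)
    for t in range(spec.n_types):
        rows = types == t
        probs[np.ix_(rows, np.arange(t * mpt, (t + 1) * mpt))] = spec.p_marker
    dense = rng.random((n, p)) < probs
    X = sp.csr_matrix(dense, dtype=np.int64)
    del dense, probs

    if spec.poisson_lift and X.nnz:
        X.data = 1 + rng.poisson(0.2, size=X.nnz)

    if spec.dropout > 0 and X.nnz:
        n_drop = int(np.floor(spec.dropout * X.nnz))
        drop_idx = rng.choice(X.nnz, size=n_drop, replace=False)
        X.data[drop_idx] = 0
        X.eliminate_zeros()

    labels = np.array([f"type_{t}" for t in types])
    adata = ad.AnnData(
        X=X,
        obs=pd.DataFrame(
            {"cell_type": labels},
            index=pd.Index([f"cell_{i}" for i in range(n)], name="cell"),
        ),
        var=pd.DataFrame(index=pd.Index([f"region_{j}" for j in range(p)], name="region")),
    )
    return adata, labels


def imbalance_profile(spec: FixtureSpec, rare_fraction: float) -> FixtureSpec:
    """Make the last type rare and renormalize the remaining proportions."""
    if not (0.0 < rare_fraction < 1.0 / spec.n_types):
        raise ValueError(f"rare_fraction must lie in (0, 1/{spec.n_types})")
    props = spec.proportions.copy()
    rest = props[:-1]
    rest = rest / rest.sum() * (1.0 - rare_fraction)
    new_props = tuple(rest) + (rare_fraction,)
    return replace(spec, type_proportions=new_props)


def write_fixture(spec: FixtureSpec, out_h5ad: str | Path, labels_tsv: str | Path | None = None) -> Path:
    """Write the fixture as h5ad plus an optional TSV of true labels."""
    adata, labels = generate_sccas(spec)
    out_h5ad = Path(out_h5ad)
    adata.write_h5ad(out_h5ad)
    if labels_tsv is not None:
        pd.DataFrame({"cell": adata.obs_names, "cell_type": labels}).to_csv(
            labels_tsv, sep="\t", index=False
        )
    return out_h5ad
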