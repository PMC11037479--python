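import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp
import anndata as ad

from carousel.simulate import FixtureSpec, generate_sccas


@pytest.fixture()
def tiny_h5ad(tmp_path):
    """25 cells x 8 regions of small integer counts, written to disk."""
    rng = np.random.default_rng(42)
    X = sp.csr_matrix(rng.integers(0, 4, size=(25, 8)))
    adata = ad.AnnData(
        X=X,
        obs=pd.DataFrame(index=[f"c{i}" for i in range(25)]),
        var=pd.DataFrame(index=[f"r{j}" for j in range(8)]),
    )
    path = tmp_path / "tiny.h5ad"
    adata.write_h5ad(path)
    return path, X


@pytest.fixture(scope="session")
def small_fixture():
    """600-cell, 3-type block fixture with its true labels (in memory)."""
    spec = FixtureSpec(
        n_cells=600, n_regions=800, n_types=3, markers_per_type=80, seed=11
    )
    adata, labels = generate_sccas(spec)
    return adata, labels


@pytest.fixture(scope="session")
def small_fixture_path(small_fixture, tmp_path_factory):
    adata, _ = small_fixture
    path = tmp_path_factory.mktemp("fx") / "small.h5ad"
    adata.write_h5ad(path)
    return path
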