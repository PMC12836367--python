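import numpy as np
import pandas as pd
import pytest
from anndata import AnnData
from scipy import sparse

import tmescope as tm


@pytest.fixture(scope="session")
def small_cohort() -> AnnData:
    """A small two-group cohort with default structure (no planted effect)."""
    config = tm.CohortConfig(
        n_samples_per_group=3, n_genes=50, cells_per_sample=150, seed=42
    )
    return tm.simulate_cohort(config)


@pytest.fixture(scope="session")
def small_tensor(small_cohort) -> tm.PseudobulkTensor:
    return tm.pseudobulk(small_cohort)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


def make_adata(counts: np.ndarray, **obs_cols) -> AnnData:
    """AnnData from a dense cells x genes integer array with default metadata."""
    n_cells, n_genes = counts.shape
    obs = pd.DataFrame(
        {
            "sample": obs_cols.get("sample", ["s1"] * n_cells),
            "cluster": obs_cols.get("cluster", ["c1"] * n_cells),
            "population": obs_cols.get("population", ["myeloid"] * n_cells),
            "condition": obs_cols.get("condition", ["WT"] * n_cells),
        },
        index=pd.Index([f"cell_{i}" for i in range(n_cells)], name="cell"),
    )
    var = pd.DataFrame(index=pd.Index([f"g{j}" for j in range(n_genes)], name="gene"))
    return AnnData(X=sparse.csr_matrix(counts.astype(np.int64)), obs=obs, var=var)
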