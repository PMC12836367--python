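"""Cell/gene QC filtering, per-cell normalization, and pseudobulk aggregation.

The single-cell container is an :class:`anndata.AnnData` with raw integer
counts in ``X`` (cells x genes) and the per-cell metadata columns
``sample``, ``cluster``, ``population`` and ``condition`` in ``obs``.

Pseudobulk values are ``log2(CPM + 1)`` of counts summed over all cells of a
(sample, cluster) group; within each sample the columns are partitioned by
cell population (myeloid / tumor / T) because the downstream min-max
normalization operates within a population.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scanpy as sc
from anndata import AnnData
from scipy import sparse

logger = logging.getLogger(__name__)

OBS_COLUMNS = ("sample", "cluster", "population", "condition")


def _require_metadata(adata: AnnData) -> None:
    missing = [c for c in OBS_COLUMNS if c not in adata.obs.columns]
    if missing:
        raise ValueError(f"cell metadata columns missing: {missing}")


def filter_cells(adata: AnnData, min_genes: int = 500, min_umi: int = 750) -> AnnData:
    """Keep cells with >= ``min_genes`` detected genes AND >= ``min_umi`` total counts.

    Thresholds are inclusive: they are the smallest admissible values.
    """
    out = adata.copy()
    n0 = out.n_obs
    # sequential application of two inclusive filters == logical AND
    sc.pp.filter_cells(out, min_genes=min_genes)
    sc.pp.filter_cells(out, min_counts=min_umi)
    if out.n_obs == 0:
        raise ValueError(
            f"no cells survive QC (min_genes={min_genes}, min_umi={min_umi})"
        )
    logger.info("filter_cells removed %d of %d cells", n0 - out.n_obs, n0)
    return out


def filter_genes(adata: AnnData, min_fraction: float = 0.001) -> AnnData:
    """Keep genes detected (count > 0) in at least ``min_fraction`` of the cells.

    The fraction refers to the cells currently in the matrix, i.e. it is
    computed after any cell filtering already applied.
    """
    if not 0.0 <= min_fraction <= 1.0:
        raise ValueError(f"min_fraction must be in [0, 1], got {min_fraction}")
    out = adata.copy()
    n0 = out.n_vars
    # inclusive cell-count threshold; the epsilon guards float round-off when
    # min_fraction * n_cells is an exact integer (0.001 is not a binary float)
    min_cells = int(np.ceil(min_fraction * out.n_obs - 1e-9))
    sc.pp.filter_genes(out, min_cells=max(min_cells, 1))
    logger.info("filter_genes removed %d of %d genes", n0 - out.n_vars, n0)
    return out


def lognormalize(adata: AnnData, scale: float = 1e4) -> AnnData:
    """Per-cell library-size normalization: ``ln(1 + scale * count / cell_total)``.

    Used for cell-level scoring only; pseudobulk has its own normalization.
    """
    totals = np.asarray(adata.X.sum(axis=1)).ravel()
    if np.any(totals == 0):
        raise ValueError("cells with zero total counts; run filter_cells first")
    out = adata.copy()
    sc.pp.normalize_total(out, target_sum=scale)
    sc.pp.log1p(out)
    return out


@dataclass
class PseudobulkTensor:
    """Per-sample gene x cell-type pseudobulk values.

    ``values`` is genes x MultiIndex(sample, population, cell_type) holding
    log2(CPM+1) (or the min-max normalized twin when ``normalized``);
    ``cell_counts`` gives the number of cells aggregated into each column.
    """

    values: pd.DataFrame
    cell_counts: pd.Series
    normalized: bool = False
    population_of: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not isinstance(self.values.columns, pd.MultiIndex):
            raise ValueError("values must have (sample, population, cell_type) columns")
        self.values.columns = self.values.columns.set_names(
            ["sample", "population", "cell_type"]
        )
        if not self.population_of:
            self.population_of = {
                ct: pop
                for (_, pop, ct) in self.values.columns
            }

    @property
    def samples(self) -> list:
        return sorted(self.values.columns.get_level_values("sample").unique())

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    def expr(self, gene: str, sample, cell_type: str) -> float:
        """Value for one gene in one cell type of one sample (NaN if the
        cell type is absent from that sample)."""
        pop = self.population_of[cell_type]
        try:
            return float(self.values.at[gene, (sample, pop, cell_type)])
        except KeyError:
            return float("nan")


def pseudobulk(adata: AnnData, min_cells_per_cluster: int = 3) -> PseudobulkTensor:
    """Aggregate raw counts per (sample, cluster), convert to CPM, log2(CPM+1).

    Clusters represented by fewer than ``min_cells_per_cluster`` cells in a
    sample, or with zero total counts, are dropped from that sample with a
    warning (they would yield degenerate pseudobulk columns).
    """
    _require_metadata(adata)
    X = adata.X
    if not sparse.issparse(X):
        X = sparse.csr_matrix(X)
    obs = adata.obs
    keys = pd.MultiIndex.from_frame(obs[["sample", "population", "cluster"]])
    codes, uniques = pd.factorize(keys, sort=True)
    n_groups = len(uniques)
    indicator = sparse.csr_matrix(
        (np.ones(adata.n_obs), (codes, np.arange(adata.n_obs))),
        shape=(n_groups, adata.n_obs),
    )
    sums = np.asarray((indicator @ X).todense(), dtype=float)  # groups x genes
    n_cells = np.bincount(codes, minlength=n_groups)

    keep = np.ones(n_groups, dtype=bool)
    totals = sums.sum(axis=1)
    for g in range(n_groups):
        if n_cells[g] < min_cells_per_cluster or totals[g] == 0:
            keep[g] = False
            warnings.warn(
                f"dropping cluster {uniques[g][2]!r} in sample {uniques[g][0]!r}: "
                f"{n_cells[g]} cells, {totals[g]:.0f} total counts"
            )
    sums = sums[keep]
    cpm = sums / sums.sum(axis=1, keepdims=True) * 1e6
    vals = np.log2(cpm + 1.0)

    cols = pd.MultiIndex.from_tuples(
        [tuple(u) for u, k in zip(uniques, keep) if k],
        names=["sample", "population", "cell_type"],
    )
    values = pd.DataFrame(vals.T, index=adata.var_names.copy(), columns=cols)
    counts = pd.Series(n_cells[keep], index=cols)
    return PseudobulkTensor(values=values, cell_counts=counts)
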