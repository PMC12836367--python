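"""Necrosis-anchored spatial statistics for spot-level transcriptomics.

Spots carry coordinates, expression, a necrosis annotation, and per-spot
cell-type deconvolution weights (inputs; deconvolution itself is upstream).
Non-necrotic spots are stratified into equal-count distance regions from the
necrotic mask; a cell type's infiltration profile is the per-region fraction
of spots whose weight exceeds the global median.  Ligand-receptor coupling
is measured by regressing spot-level receptor expression on the "niche
ligand" — the mean ligand expression over a spot's 20 nearest neighbors
(self excluded) — and reporting the adjusted R^2, separately for the
perinecrotic half (50% of non-necrotic spots closest to necrosis) and the
distant rest.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy import stats

__all__ = [
    "SpatialDataset",
    "RegionStrata",
    "distance_to_necrosis",
    "stratify",
    "high_infiltration_profile",
    "smooth_expression",
    "niche_ligand",
    "adjusted_r2",
    "region_contrast",
]


@dataclass
class SpatialDataset:
    """Spot table: coordinates, necrosis mask, expression, deconvolution weights.

    All four frames/series share the spot-id index.  ``expression`` is
    spots x genes (normalized scale); ``weights`` rows are nonnegative and
    sum to one.
    """

    spots: pd.DataFrame          # columns: x, y (and optional annotation)
    necrotic: pd.Series          # bool per spot
    expression: pd.DataFrame     # spots x genes
    weights: pd.DataFrame        # spots x cell types
    truth: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        idx = self.spots.index
        for name, other in (
            ("necrotic", self.necrotic.index),
            ("expression", self.expression.index),
            ("weights", self.weights.index),
        ):
            if not idx.equals(other):
                raise ValueError(f"{name} index does not match spot index")
        if not np.isfinite(self.spots[["x", "y"]].to_numpy()).all():
            raise ValueError("non-finite spot coordinates")
        w = self.weights.to_numpy()
        if (w < -1e-9).any():
            raise ValueError("negative deconvolution weights")
        if np.any(np.abs(w.sum(axis=1) - 1.0) > 1e-6):
            raise ValueError("deconvolution weights must sum to 1 per spot")

    @property
    def coords(self) -> np.ndarray:
        return self.spots[["x", "y"]].to_numpy(dtype=float)

    @property
    def non_necrotic_ids(self) -> pd.Index:
        return self.spots.index[~self.necrotic.to_numpy()]


def distance_to_necrosis(d: SpatialDataset) -> pd.Series:
    """Minimum Euclidean distance from each non-necrotic spot to any necrotic spot."""
    nec = d.necrotic.to_numpy(bool)
    if not nec.any():
        raise ValueError("dataset contains no necrotic spots")
    if nec.all():
        raise ValueError("dataset contains no non-necrotic spots")
    tree = cKDTree(d.coords[nec])
    dist, _ = tree.query(d.coords[~nec], k=1)
    return pd.Series(dist, index=d.spots.index[~nec], name="distance")


@dataclass
class RegionStrata:
    """Equal-count distance strata over non-necrotic spots (1 = closest)."""

    labels: pd.Series            # spot id -> region in 1..n_regions
    n_regions: int

    def region_ids(self, region: int) -> pd.Index:
        return self.labels.index[self.labels == region]


def stratify(distances: pd.Series, n_regions: int = 10) -> RegionStrata:
    """Equal-count quantile strata of distance-to-necrosis.

    Spots are sorted by (distance, spot id) — the id breaks ties
    deterministically — and split into ``n_regions`` contiguous chunks of
    near-equal size, earlier (closer) chunks taking any remainder.
    """
    if n_regions < 1 or n_regions > len(distances):
        raise ValueError("n_regions must be in [1, n_spots]")
    order = distances.reset_index()
    order.columns = ["spot", "distance"]
    order = order.sort_values(["distance", "spot"], kind="mergesort")
    labels = np.empty(len(order), dtype=int)
    for r, chunk in enumerate(np.array_split(np.arange(len(order)), n_regions)):
        labels[chunk] = r + 1
    return RegionStrata(
        labels=pd.Series(labels, index=pd.Index(order["spot"], name="spot")),
        n_regions=n_regions,
    )


def high_infiltration_profile(
    d: SpatialDataset, strata: RegionStrata, cell_type: str
) -> pd.Series:
    """Per-region fraction of spots with 'high' infiltration of a cell type.

    High = deconvolution weight strictly greater than the median weight over
    all non-necrotic spots.  Returns all regions; the first five (closest to
    necrosis) are the conventionally reported ones.
    """
    w = d.weights.loc[strata.labels.index, cell_type]
    med = float(w.median())
    high = w > med
    return high.groupby(strata.labels).mean().rename("high_fraction")


def _knn_indices(coords: np.ndarray, k: int, include_self: bool) -> np.ndarray:
    tree = cKDTree(coords)
    if include_self:
        _, idx = tree.query(coords, k=k + 1)
        return idx
    _, idx = tree.query(coords, k=k + 1)
    return idx[:, 1:]


def smooth_expression(d: SpatialDataset, k: int = 6) -> pd.DataFrame:
    """Replace each spot's expression by the mean over itself and its k
    nearest neighbors (signal-to-noise smoothing across all spots)."""
    if k >= len(d.spots):
        raise ValueError("k must be smaller than the number of spots")
    idx = _knn_indices(d.coords, k, include_self=True)
    vals = d.expression.to_numpy(dtype=float)
    return pd.DataFrame(
        vals[idx].mean(axis=1), index=d.expression.index,
        columns=d.expression.columns,
    )


def knn_mean(coords: np.ndarray, values: np.ndarray, k: int) -> np.ndarray:
    """Mean of ``values`` over each point's k nearest neighbors, self excluded."""
    if k >= len(coords):
        raise ValueError(f"need more than k={k} spots for a self-excluded mean")
    idx = _knn_indices(coords, k, include_self=False)
    return np.asarray(values, dtype=float)[idx].mean(axis=1)


def niche_ligand(d: SpatialDataset, ligand: str, k: int = 20) -> pd.Series:
    """Niche-ligand value: mean ligand expression over the k nearest
    non-necrotic neighboring spots (self excluded), per non-necrotic spot."""
    ids = d.non_necrotic_ids
    coords = d.spots.loc[ids, ["x", "y"]].to_numpy(dtype=float)
    vals = d.expression.loc[ids, ligand].to_numpy(dtype=float)
    return pd.Series(knn_mean(coords, vals, k), index=ids, name="niche_ligand")


def adjusted_r2(y, x) -> float:
    """Adjusted R^2 of the simple linear regression y ~ x:
    ``1 - (1 - R^2)(n - 1)/(n - 2)``.  NaN for n < 3 or a constant predictor."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n < 3 or np.all(x == x[0]) or np.all(y == y[0]):
        return float("nan")
    r = stats.pearsonr(x, y).statistic
    r2 = r * r
    return float(1.0 - (1.0 - r2) * (n - 1) / (n - 2))


def perinecrotic_split(d: SpatialDataset) -> tuple[pd.Index, pd.Index]:
    """Perinecrotic = the ceil(n/2) non-necrotic spots closest to necrosis
    (ties broken by spot id); distant = the rest."""
    dist = distance_to_necrosis(d)
    order = dist.reset_index()
    order.columns = ["spot", "distance"]
    order = order.sort_values(["distance", "spot"], kind="mergesort")
    n_peri = int(np.ceil(len(order) / 2))
    peri = pd.Index(order["spot"].iloc[:n_peri])
    distant = pd.Index(order["spot"].iloc[n_peri:])
    return peri, distant


def region_contrast(
    d: SpatialDataset, ligand: str, receptor: str, k_niche: int = 20
) -> tuple[float, float]:
    """Adjusted R^2 of receptor ~ niche-ligand, separately for the
    perinecrotic and distant halves of the non-necrotic spots."""
    peri, distant = perinecrotic_split(d)
    niche = niche_ligand(d, ligand, k=k_niche)
    rec = d.expression[receptor]
    r2_peri = adjusted_r2(rec.loc[peri], niche.loc[peri])
    r2_dist = adjusted_r2(rec.loc[distant], niche.loc[distant])
    return r2_peri, r2_dist
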