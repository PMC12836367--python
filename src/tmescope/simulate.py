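"""Synthetic data with the statistical structure the analyses assume.

Three generators:

* :func:`simulate_cohort` — a multi-sample single-cell cohort with two
  condition groups ("WT" for IDH-wild-type-like, "MUT" for IDH-mutant-like),
  negative-binomial (gamma-Poisson) counts, cluster-specific mean profiles,
  and optional planted ligand-receptor coupling: a pair's ligand mean is
  multiplied in cell type A and its receptor mean in cell type B, only in
  the designated condition group.
* :func:`simulate_trajectory` — per-cell expression drawn from the
  three-hierarchy B-spline model with known parameters (beta, tau, sigma^2),
  pseudotime uniform on [0, 1].
* :func:`simulate_spatial` — a square spot lattice with a necrotic disk,
  per-spot cell-type weights decaying (or growing) with distance from
  necrosis, a smooth ligand field, and receptor expression coupled to the
  spot's niche-ligand value inside a designated region.

Every generator takes a single integer seed and is fully reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from anndata import AnnData
from scipy import sparse

from .trajectory import BasisSpec, build_basis
from .spatial import SpatialDataset, knn_mean

__all__ = [
    "PlantedPair",
    "CohortConfig",
    "TrajectorySimConfig",
    "SpatialSimConfig",
    "PseudotimeDataset",
    "simulate_cohort",
    "simulate_trajectory",
    "simulate_spatial",
]


# ---------------------------------------------------------------------------
# cohort


@dataclass(frozen=True)
class PlantedPair:
    """A ligand-receptor pair with elevated coupling in one condition group."""

    ligand: str
    receptor: str
    cell_a: str
    cell_b: str
    group: str = "WT"
    multiplier: float = 8.0

    def __post_init__(self) -> None:
        if self.multiplier < 1:
            raise ValueError("effect multiplier must be >= 1")
        if self.group not in ("WT", "MUT"):
            raise ValueError("group must be 'WT' or 'MUT'")


@dataclass
class CohortConfig:
    """Study conditions for the interaction-scoring cohort.

    Defaults emulate a two-group patient cohort at desk scale: 6 samples per
    condition group, three cell types in each of the myeloid / tumor / T
    populations, modest sequencing depth, and negative-binomial
    overdispersion typical of droplet scRNA-seq.
    """

    n_samples_per_group: int = 6
    n_cell_types: dict = field(
        default_factory=lambda: {"myeloid": 3, "tumor": 3, "T": 3}
    )
    n_genes: int = 250
    cells_per_sample: int = 300
    baseline_mean: float = 0.5
    planted_pairs: list = field(default_factory=list)
    dispersion: float = 0.3
    celltype_logsd: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_samples_per_group, self.n_genes, self.cells_per_sample) <= 0:
            raise ValueError("all cohort dimensions must be positive")
        if any(v <= 0 for v in self.n_cell_types.values()):
            raise ValueError("each population needs a positive cell-type count")
        if self.baseline_mean < 0 or self.dispersion <= 0:
            raise ValueError("baseline_mean must be >= 0 and dispersion > 0")

    @property
    def cluster_names(self) -> list[str]:
        names = [
            f"{pop}_{i + 1}"
            for pop, k in self.n_cell_types.items()
            for i in range(k)
        ]
        if len(set(names)) != len(names):
            raise ValueError("duplicate cluster names")
        return names

    @property
    def gene_names(self) -> list[str]:
        return [f"G{i + 1:04d}" for i in range(self.n_genes)]


def simulate_cohort(config: CohortConfig) -> AnnData:
    """Negative-binomial cohort counts as an AnnData (cells x genes).

    ``obs`` carries sample, cluster, population and condition; ``uns`` keeps
    the planted pairs.  Identical configs (same seed) produce byte-identical
    matrices.
    """
    rng = np.random.default_rng(config.seed)
    clusters = config.cluster_names
    pop_of = {
        f"{pop}_{i + 1}": pop
        for pop, k in config.n_cell_types.items()
        for i in range(k)
    }
    genes = config.gene_names
    gene_idx = {g: i for i, g in enumerate(genes)}
    clus_idx = {c: i for i, c in enumerate(clusters)}

    base = rng.gamma(shape=2.0, scale=config.baseline_mean / 2.0, size=config.n_genes)
    profile = base[:, None] * np.exp(
        rng.normal(0.0, config.celltype_logsd, size=(config.n_genes, len(clusters)))
    )

    samples = [f"WT_{i + 1}" for i in range(config.n_samples_per_group)] + [
        f"MUT_{i + 1}" for i in range(config.n_samples_per_group)
    ]
    condition_of = {s: s.split("_")[0] for s in samples}

    for pp in config.planted_pairs:
        for g in (pp.ligand, pp.receptor):
            if g not in gene_idx:
                raise ValueError(f"planted gene {g!r} not among simulated genes")
        for c in (pp.cell_a, pp.cell_b):
            if c not in clus_idx:
                raise ValueError(f"planted cell type {c!r} not among clusters")

    blocks = []
    obs_rows = []
    for s in samples:
        props = rng.dirichlet(np.full(len(clusters), 10.0))
        counts_per_cluster = rng.multinomial(config.cells_per_sample, props)
        mu_sample = profile.copy()
        for pp in config.planted_pairs:
            if condition_of[s] == pp.group:
                mu_sample[gene_idx[pp.ligand], clus_idx[pp.cell_a]] *= pp.multiplier
                mu_sample[gene_idx[pp.receptor], clus_idx[pp.cell_b]] *= pp.multiplier
        for c, n_c in zip(clusters, counts_per_cluster):
            if n_c == 0:
                continue
            mu = mu_sample[:, clus_idx[c]]  # per-gene mean
            lam = rng.gamma(
                shape=1.0 / config.dispersion,
                scale=mu * config.dispersion,
                size=(n_c, config.n_genes),
            )
            blocks.append(rng.poisson(lam))
            obs_rows.extend((s, c, pop_of[c], condition_of[s]) for _ in range(n_c))

    X = sparse.csr_matrix(np.concatenate(blocks, axis=0))
    obs = pd.DataFrame(
        obs_rows, columns=["sample", "cluster", "population", "condition"]
    )
    obs.index = pd.Index([f"cell_{i + 1}" for i in range(len(obs))], name="cell")
    adata = AnnData(X=X, obs=obs, var=pd.DataFrame(index=pd.Index(genes, name="gene")))
    adata.uns["planted_pairs"] = [vars(pp).copy() for pp in config.planted_pairs]
    return adata


# ---------------------------------------------------------------------------
# trajectory


@dataclass
class TrajectorySimConfig:
    """Study conditions for the pseudotime generator.

    The basis has ``n_knots + degree + 1`` functions (default 7: cubic with
    three interior knots).  ``amplitude`` is the max-minus-min range, on the
    standardized expression scale, of a signal gene's population curve;
    ``beta`` may instead give explicit coefficients (n_signal_genes x N).
    ``tau`` is the between-sample random-effect variance and ``sigma2`` the
    within-sample noise variance (scalar, or one value per sample).
    """

    n_samples: int = 4
    cells_per_sample: int = 500
    n_knots: int = 3
    degree: int = 3
    n_null_genes: int = 0
    n_signal_genes: int = 1
    amplitude: float = 1.0
    tau: float = 0.05
    sigma2: float | np.ndarray = 0.09
    beta: np.ndarray | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.tau < 0:
            raise ValueError("tau must be >= 0")
        if np.any(np.asarray(self.sigma2) <= 0):
            raise ValueError("sigma2 must be > 0")
        if self.beta is not None:
            self.beta = np.atleast_2d(np.asarray(self.beta, dtype=float))
            if self.beta.shape[1] != self.n_basis:
                raise ValueError(
                    f"beta has {self.beta.shape[1]} columns, basis has "
                    f"{self.n_basis} functions (n_knots + degree + 1)"
                )
            if self.beta.shape[0] != self.n_signal_genes:
                raise ValueError("beta needs one row per signal gene")

    @property
    def n_basis(self) -> int:
        return self.n_knots + self.degree + 1

    @property
    def sigma2_per_sample(self) -> np.ndarray:
        s2 = np.asarray(self.sigma2, dtype=float)
        if s2.ndim == 0:
            return np.full(self.n_samples, float(s2))
        if len(s2) != self.n_samples:
            raise ValueError("sigma2 must be scalar or one value per sample")
        return s2


@dataclass
class PseudotimeDataset:
    """Simulated expression along pseudotime plus the generating truth."""

    expression: pd.DataFrame      # genes x cells
    pseudotime: pd.Series         # per cell, in [0, 1]
    samples: pd.Series            # per cell
    spec: BasisSpec
    true_beta: pd.DataFrame       # genes x N
    tau: float
    sigma2: np.ndarray
    is_signal: pd.Series


def _random_signal_beta(rng, spec: BasisSpec, amplitude: float) -> np.ndarray:
    """Random smooth coefficients rescaled so the curve's range is `amplitude`."""
    grid = spec.design_matrix(np.linspace(0, 1, 200))
    b = rng.normal(size=spec.n_basis)
    f = grid @ b
    span = f.max() - f.min()
    if span == 0:
        return np.zeros_like(b)
    b = b * (amplitude / span)
    f = grid @ b
    return b - f.mean()  # center the curve on the standardized scale


def simulate_trajectory(config: TrajectorySimConfig) -> PseudotimeDataset:
    """Draw e_gcs = sum_i phi_i(t_cs) a_igs + eps with a_gs ~ N(beta_g, tau I).

    Null genes are structure-free (beta = 0 and no sample-level random
    effect: pure N(0, sigma^2) noise); signal genes use explicit
    ``config.beta`` rows or random smooth curves of the configured amplitude
    plus a_s ~ N(beta, tau I) sample deviations.  Pseudotime is uniform on
    [0, 1] (the ordering is an input to the analysis, so any ordering works
    for testing).
    """
    rng = np.random.default_rng(config.seed)
    S = config.n_samples
    n_cells = S * config.cells_per_sample
    t = rng.uniform(0.0, 1.0, n_cells)
    sample_labels = np.repeat(
        [f"S{i + 1}" for i in range(S)], config.cells_per_sample
    )
    spec, phi = build_basis(t, config.n_knots, config.degree)

    n_genes = config.n_null_genes + config.n_signal_genes
    betas = np.zeros((n_genes, spec.n_basis))
    is_signal = np.zeros(n_genes, dtype=bool)
    for gi in range(config.n_signal_genes):
        g = config.n_null_genes + gi
        is_signal[g] = True
        if config.beta is not None:
            betas[g] = config.beta[gi]
        else:
            betas[g] = _random_signal_beta(rng, spec, config.amplitude)

    s2 = config.sigma2_per_sample
    genes = [f"G{i + 1:04d}" for i in range(n_genes)]
    E = np.empty((n_genes, n_cells))
    for si, s in enumerate([f"S{i + 1}" for i in range(S)]):
        mask = sample_labels == s
        phi_s = phi[mask]
        u = rng.normal(0.0, math.sqrt(config.tau), size=(n_genes, spec.n_basis))
        u[~is_signal] = 0.0  # null genes carry no structure at any hierarchy
        a = betas + u                                     # genes x N
        eps = rng.normal(0.0, math.sqrt(s2[si]), size=(n_genes, mask.sum()))
        E[:, mask] = a @ phi_s.T + eps

    cells = pd.Index([f"cell_{i + 1}" for i in range(n_cells)], name="cell")
    return PseudotimeDataset(
        expression=pd.DataFrame(E, index=pd.Index(genes, name="gene"), columns=cells),
        pseudotime=pd.Series(t, index=cells, name="pseudotime"),
        samples=pd.Series(sample_labels, index=cells, name="sample"),
        spec=spec,
        true_beta=pd.DataFrame(betas, index=pd.Index(genes, name="gene")),
        tau=config.tau,
        sigma2=s2,
        is_signal=pd.Series(is_signal, index=pd.Index(genes, name="gene")),
    )


# ---------------------------------------------------------------------------
# spatial


@dataclass
class SpatialSimConfig:
    """Study conditions for the spot-lattice generator.

    ``decay_lengths`` maps simulated cell types to length scales lambda for
    weights proportional to exp(-d / lambda): positive lambda decays with
    distance from necrosis, negative grows, ``inf`` is flat.  The
    ligand-receptor coupling (receptor = strength x niche-ligand + noise)
    applies inside ``coupling_region`` ("perinecrotic" or "global"); outside
    it the receptor is independent noise.
    """

    shape: tuple[int, int] = (40, 40)
    necrosis_center: tuple[float, float] | None = None
    necrosis_radius: float = 5.0
    decay_lengths: dict = field(
        default_factory=lambda: {
            "EMDSC": 6.0,
            "T4": 8.0,
            "tumor": -8.0,
            "stroma": math.inf,
        }
    )
    coupling_strength: float = 1.0
    coupling_region: str = "perinecrotic"
    noise_sd: float = 0.1
    weight_noise_sd: float = 0.1
    k_niche: int = 20
    ligand: str = "LIG"
    receptor: str = "REC"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.coupling_region not in ("perinecrotic", "global"):
            raise ValueError("coupling_region must be 'perinecrotic' or 'global'")
        if self.noise_sd < 0 or self.weight_noise_sd < 0:
            raise ValueError("noise standard deviations must be >= 0")
        if min(self.shape) < 2:
            raise ValueError("grid must be at least 2 x 2")


def simulate_spatial(config: SpatialSimConfig) -> SpatialDataset:
    """Spot grid with a necrotic disk, decaying weights, and coupled expression.

    The ligand field is a smooth low-frequency surface plus noise; the
    receptor equals ``coupling_strength x niche-ligand + noise`` inside the
    coupling region (niche = mean ligand over 20 nearest non-necrotic
    neighbors, self excluded — the same definition the analysis uses) and is
    independent noise elsewhere.  ``truth`` records the planted parameters
    and the realized niche values.
    """
    rng = np.random.default_rng(config.seed)
    rows, cols = config.shape
    yy, xx = np.mgrid[0:rows, 0:cols]
    x = xx.ravel().astype(float)
    y = yy.ravel().astype(float)
    n = len(x)
    ids = pd.Index([f"spot_{i + 1:04d}" for i in range(n)], name="spot")

    center = config.necrosis_center or ((cols - 1) / 2.0, (rows - 1) / 2.0)
    d_center = np.hypot(x - center[0], y - center[1])
    necrotic = d_center <= config.necrosis_radius
    if not necrotic.any():
        raise ValueError("necrotic radius produces no necrotic spots")
    if necrotic.all():
        raise ValueError("necrotic radius covers the entire grid")

    # distance from necrosis for every spot (0 inside the mask)
    from scipy.spatial import cKDTree

    tree = cKDTree(np.c_[x, y][necrotic])
    dist = np.zeros(n)
    dist[~necrotic], _ = tree.query(np.c_[x, y][~necrotic], k=1)

    # deconvolution weights ~ exp(-d / lambda), lognormal noise, renormalized
    raw = {}
    for ct, lam in config.decay_lengths.items():
        if math.isinf(lam):
            w = np.ones(n)
        else:
            w = np.exp(-dist / lam)
        if config.weight_noise_sd > 0:
            w = w * np.exp(rng.normal(0.0, config.weight_noise_sd, n))
        raw[ct] = w
    weights = pd.DataFrame(raw, index=ids)
    weights = weights.div(weights.sum(axis=1), axis=0)

    # smooth ligand field: two random low-frequency waves + noise
    scale = max(rows, cols)
    k1 = rng.uniform(0.5, 1.5, 2) / scale
    k2 = rng.uniform(0.5, 1.5, 2) / scale
    phase = rng.uniform(0, 2 * np.pi, 2)
    ligand = (
        3.0
        + np.sin(2 * np.pi * (k1[0] * x + k1[1] * y) + phase[0])
        + np.cos(2 * np.pi * (k2[0] * x - k2[1] * y) + phase[1])
        + rng.normal(0.0, config.noise_sd, n)
    )

    # niche over non-necrotic spots with the analysis' own definition
    non_nec = ~necrotic
    niche = np.full(n, np.nan)
    niche[non_nec] = knn_mean(
        np.c_[x, y][non_nec], ligand[non_nec], k=config.k_niche
    )

    receptor = 1.0 + rng.normal(0.0, config.noise_sd, n)
    if config.coupling_region == "global":
        region_mask = non_nec
    else:
        order = np.lexsort((ids[non_nec], dist[non_nec]))
        n_peri = int(np.ceil(non_nec.sum() / 2))
        peri_pos = np.flatnonzero(non_nec)[order[:n_peri]]
        region_mask = np.zeros(n, dtype=bool)
        region_mask[peri_pos] = True
    receptor[region_mask] = (
        config.coupling_strength * niche[region_mask]
        + rng.normal(0.0, config.noise_sd, int(region_mask.sum()))
    )

    region = np.where(necrotic, "necrosis",
                      np.where(region_mask, "perinecrotic", "distant"))
    spots = pd.DataFrame({"x": x, "y": y, "region": region}, index=ids)
    expression = pd.DataFrame(
        {config.ligand: ligand, config.receptor: receptor}, index=ids
    )
    return SpatialDataset(
        spots=spots,
        necrotic=pd.Series(necrotic, index=ids, name="necrotic"),
        expression=expression,
        weights=weights,
        truth={
            "coupling_strength": config.coupling_strength,
            "coupling_region": config.coupling_region,
            "noise_sd": config.noise_sd,
            "niche": pd.Series(niche, index=ids, name="niche"),
            "distance": pd.Series(dist, index=ids, name="distance"),
        },
    )
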