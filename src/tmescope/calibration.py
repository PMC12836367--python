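"""Replicated simulation experiments at the package's study conditions.

Each function simulates data with :mod:`tmescope.simulate` at its default
conditions, runs the corresponding analysis end to end, and returns summary
operating characteristics (type-I error, power, recovery error).  They back
both the acceptance checks and the reproducibility script.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from . import interaction as tinter
from . import preprocess as tprep
from . import spatial as tspat
from . import trajectory as ttraj
from .simulate import (
    CohortConfig,
    PlantedPair,
    SpatialSimConfig,
    TrajectorySimConfig,
    simulate_cohort,
    simulate_spatial,
    simulate_trajectory,
)


def _random_pairs(rng, genes, clusters_a, clusters_b, n_pairs):
    """Random LR records over distinct genes and given cluster panels."""
    seen = set()
    lig, rec = [], []
    while len(lig) < n_pairs:
        i, j = rng.choice(len(genes), 2, replace=False)
        if (i, j) not in seen:
            seen.add((i, j))
            lig.append(genes[i])
            rec.append(genes[j])
    return pd.DataFrame(
        {
            "ligand": lig,
            "receptor": rec,
            "cell_a": rng.choice(clusters_a, n_pairs),
            "cell_b": rng.choice(clusters_b, n_pairs),
        }
    )


def run_cohort_pipeline(config: CohortConfig, pairs: pd.DataFrame) -> pd.DataFrame:
    """simulate -> QC -> pseudobulk -> min-max -> NIS -> group test -> BH."""
    adata = simulate_cohort(config)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        adata = tprep.filter_genes(tprep.filter_cells(adata, 1, 1))
        tensor = tprep.pseudobulk(adata)
        norm = tinter.minmax_normalize(tensor)
        groups = (
            adata.obs.drop_duplicates("sample").set_index("sample")["condition"]
        )
        return tinter.build_interaction_table(norm, pairs, groups)


def interaction_null_calibration(
    n_reps: int = 100, n_pairs: int = 200, seed: int = 0
) -> dict:
    """Fraction of records called significant on cohorts with no planted effect."""
    rng = np.random.default_rng(seed)
    n_sig = n_total = 0
    for _ in range(n_reps):
        config = CohortConfig(seed=int(rng.integers(2**31)))
        pairs = _random_pairs(
            rng, config.gene_names, config.cluster_names, config.cluster_names,
            n_pairs,
        )
        table = run_cohort_pipeline(config, pairs)
        n_sig += int(table["significant"].sum())
        n_total += len(table)
    return {"significant_fraction": n_sig / n_total, "n_records": n_total}


def interaction_planted_power(
    n_reps: int = 100, n_pairs: int = 200, multiplier: float = 8.0, seed: int = 0
) -> dict:
    """Detection of one planted pair (ligand up in cell A, receptor up in
    cell B, WT group only) across replicate cohorts.

    Reports the fraction of replicates in which the planted record is called
    significant (joint-BH FDR < 0.05 and enrichment score > 0.3) and, as an
    auxiliary diagnostic, detection at the raw p < 0.05 & ES > 0.3 level.
    """
    rng = np.random.default_rng(seed)
    detected = raw_detected = 0
    es_values = []
    for _ in range(n_reps):
        base = CohortConfig(seed=int(rng.integers(2**31)))
        pairs = _random_pairs(
            rng, base.gene_names, base.cluster_names, base.cluster_names, n_pairs
        )
        planted = PlantedPair(
            ligand=pairs.loc[0, "ligand"],
            receptor=pairs.loc[0, "receptor"],
            cell_a=pairs.loc[0, "cell_a"],
            cell_b=pairs.loc[0, "cell_b"],
            group="WT",
            multiplier=multiplier,
        )
        base.planted_pairs = [planted]
        table = run_cohort_pipeline(base, pairs)
        row = table.iloc[0]
        es_values.append(row["enrichment_score"])
        detected += bool(row["significant"])
        raw_detected += bool(
            (row["p_value"] < 0.05) & (row["enrichment_score"] > 0.3)
        )
    return {
        "detection_rate": detected / n_reps,
        "raw_detection_rate": raw_detected / n_reps,
        "mean_enrichment_score": float(np.mean(es_values)),
    }


def trajectory_beta_recovery(
    n_genes: int = 16,
    amplitude: float = 3.0,
    seed: int = 0,
) -> dict:
    """Relative L2 error of beta-hat on data simulated from the model.

    Conditions: S = 4 samples, 2000 cells, cubic basis with N = 7,
    sigma = 0.3, tau = 0.05; signal curves span ``amplitude`` standard
    deviations (strong, well-identified genes, so the error reflects the
    estimator rather than signal weakness).  Fits run unstandardized because
    the truth is known on the simulated scale.
    """
    config = TrajectorySimConfig(
        n_samples=4, cells_per_sample=500, n_knots=3, degree=3,
        n_null_genes=0, n_signal_genes=n_genes, amplitude=amplitude,
        tau=0.05, sigma2=0.09, seed=seed,
    )
    ds = simulate_trajectory(config)
    t = ds.pseudotime.to_numpy()
    s = ds.samples.to_numpy()
    errors = []
    monotone = True
    for g in ds.expression.index:
        fit = ttraj.fit_em(ds.expression.loc[g].to_numpy(), t, s, ds.spec)
        b = ds.true_beta.loc[g].to_numpy()
        errors.append(np.linalg.norm(fit.beta - b) / np.linalg.norm(b))
        monotone &= bool(np.all(np.diff(fit.loglik_trace) >= -1e-8))
    return {
        "mean_relative_l2_error": float(np.mean(errors)),
        "max_relative_l2_error": float(np.max(errors)),
        "loglik_monotone": monotone,
    }


def trajectory_test_calibration(
    n_null: int = 200,
    n_signal: int = 20,
    n_perm: int = 100,
    cells_per_sample: int = 500,
    amplitude: float = 1.0,
    seed: int = 0,
) -> dict:
    """Null p-value uniformity and power of the trajectory permutation test.

    Null genes are pure noise; signal genes have curve amplitude 1.0 (SD
    units), tau = 0.05, sigma = 0.3, S = 4.  Significance is BH-adjusted
    p < 0.05 over the whole gene family.
    """
    config = TrajectorySimConfig(
        n_samples=4, cells_per_sample=cells_per_sample, n_knots=3, degree=3,
        n_null_genes=n_null, n_signal_genes=n_signal, amplitude=amplitude,
        tau=0.05, sigma2=0.09, seed=seed,
    )
    ds = simulate_trajectory(config)
    t = ds.pseudotime.to_numpy()
    s = ds.samples.to_numpy()
    E = ds.expression.to_numpy()
    E = (E - E.mean(axis=1, keepdims=True)) / E.std(axis=1, keepdims=True)
    rng = np.random.default_rng(seed + 1)
    pvals = np.empty(len(E))
    for gi in range(len(E)):
        fit = ttraj.fit_em(E[gi], t, s, ds.spec)
        pvals[gi], _ = ttraj.permutation_test(
            E[gi], t, s, fit, n_perm=n_perm, seed=int(rng.integers(2**31))
        )
    is_signal = ds.is_signal.to_numpy()
    adj = tinter.bh_adjust(pvals)
    null_p = pvals[~is_signal]
    ks = stats.kstest(null_p, "uniform")
    return {
        "ks_stat": float(ks.statistic),
        "ks_pvalue": float(ks.pvalue),
        "null_bh_positive_fraction": float(np.mean(adj[~is_signal] < 0.05)),
        "power": float(np.mean(adj[is_signal] < 0.05)) if is_signal.any() else None,
        "null_pvalues": null_p,
    }


def spatial_recovery(n_seeds: int = 100, seed: int = 0) -> dict:
    """Region contrast and theoretical-R^2 recovery across replicate grids.

    Conditions: 40 x 40 grid, necrotic disk of radius 5, perinecrotic-only
    coupling with slope 1 and noise sd 0.1.  The theoretical adjusted R^2 is
    slope^2 var(niche) / (slope^2 var(niche) + sigma^2) with the empirical
    niche variance of the perinecrotic spots.
    """
    rng = np.random.default_rng(seed)
    peri_wins = 0
    r2_peri_all, r2_gap = [], []
    monotone_first5 = True
    for _ in range(n_seeds):
        config = SpatialSimConfig(seed=int(rng.integers(2**31)))
        d = simulate_spatial(config)
        r2_peri, r2_dist = tspat.region_contrast(d, config.ligand, config.receptor)
        peri_wins += bool(r2_peri > r2_dist)
        niche = d.truth["niche"][d.spots["region"] == "perinecrotic"]
        sv = config.coupling_strength**2 * float(niche.var())
        theory = sv / (sv + config.noise_sd**2)
        r2_peri_all.append(r2_peri)
        r2_gap.append(r2_peri - theory)
        dist = tspat.distance_to_necrosis(d)
        profile = tspat.high_infiltration_profile(
            d, tspat.stratify(dist, 10), "EMDSC"
        )
        first5 = profile.loc[1:5].to_numpy()
        monotone_first5 &= bool(np.all(np.diff(first5) <= 1e-12))
    return {
        "frac_peri_gt_distant": peri_wins / n_seeds,
        "mean_r2_peri": float(np.mean(r2_peri_all)),
        "max_abs_theory_gap": float(np.max(np.abs(r2_gap))),
        "profile_monotone_first5": monotone_first5,
    }
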