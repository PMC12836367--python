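"""Normalized interaction score (NIS) between cell types and group testing.

The NIS for a ligand-receptor pair between cell type A and cell type B in a
sample is the product of the min-max normalized pseudobulk expression of the
ligand in A and the receptor in B.  Min-max normalization runs across the
cell types of one population (myeloid / tumor / T) within one sample, so the
highest-expressing cell type gets 1 and the lowest gets 0 — the score favors
cell-type-specific expression over universally high expression.

Group comparison (IDH-WT vs IDH-mutant) uses the two-sided Wilcoxon rank-sum
test per record, an enrichment score mean(NIS | WT) - mean(NIS | MUT), and a
joint Benjamini-Hochberg adjustment over every record tested in one run;
records with FDR < 0.05 and enrichment score > 0.3 are called significant.
"""

from __future__ import annotations

import warnings
from dataclasses import replace

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .preprocess import PseudobulkTensor

__all__ = [
    "minmax_normalize",
    "interaction_score",
    "test_group_difference",
    "bh_adjust",
    "build_interaction_table",
    "cross_sample_correlation",
]


def minmax_normalize(tensor: PseudobulkTensor) -> PseudobulkTensor:
    """Min-max normalize each gene across cell types, within (sample, population).

    Genes constant across the cell types of a population (max == min) map to
    0 everywhere: a gene expressed equally in all cell types carries no
    cell-type-specific signal in this framework.
    """
    if tensor.normalized:
        raise ValueError("tensor is already min-max normalized")
    vals = tensor.values
    out_df = pd.DataFrame(
        np.empty_like(vals.values), index=vals.index, columns=vals.columns
    )
    sample_pop = vals.columns.droplevel("cell_type")
    for sample, pop in sample_pop.unique():
        block = vals.loc[:, (sample_pop.get_level_values("sample") == sample)
                         & (sample_pop.get_level_values("population") == pop)]
        if block.shape[1] < 2:
            raise ValueError(
                f"population {pop!r} has a single cell type in sample {sample!r}; "
                "min-max normalization is undefined"
            )
        lo = block.min(axis=1)
        span = block.max(axis=1) - lo
        norm = block.sub(lo, axis=0).div(span.where(span > 0), axis=0)
        out_df.loc[:, block.columns] = norm.fillna(0.0).values
    return replace(tensor, values=out_df, normalized=True)


def interaction_score(
    norm: PseudobulkTensor,
    ligand: str,
    cell_a: str,
    receptor: str,
    cell_b: str,
    sample,
) -> float:
    """NIS = norm_pb_expr(ligand, cell A) * norm_pb_expr(receptor, cell B)."""
    if not norm.normalized:
        raise ValueError("interaction_score requires a min-max normalized tensor")
    for gene in (ligand, receptor):
        if gene not in norm.values.index:
            raise KeyError(f"gene {gene!r} not present in pseudobulk tensor")
    return norm.expr(ligand, sample, cell_a) * norm.expr(receptor, sample, cell_b)


def _wilcoxon_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided Wilcoxon rank-sum p: exact for combined n <= 20 without ties,
    else normal approximation with tie and continuity correction."""
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return 1.0
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (len(pooled) <= 20 and not has_ties) else "asymptotic"
    return float(
        stats.mannwhitneyu(x, y, alternative="two-sided", method=method).pvalue
    )


def test_group_difference(scores: pd.Series, groups: pd.Series) -> tuple[float, float]:
    """Enrichment score and Wilcoxon p for one record.

    ``scores`` is indexed by sample; ``groups`` maps sample -> "WT"/"MUT".
    Returns ``(enrichment_score, p_value)`` with the enrichment score
    oriented as mean(WT) - mean(MUT).  If either group has fewer than two
    scored samples the p-value is NaN (flagged, not silently dropped).
    """
    scores = scores.dropna()
    g = groups.reindex(scores.index)
    wt = scores[g == "WT"].to_numpy(float)
    mut = scores[g == "MUT"].to_numpy(float)
    if len(wt) == 0 or len(mut) == 0:
        raise ValueError("both condition groups must be nonempty")
    es = float(wt.mean() - mut.mean())
    if len(wt) < 2 or len(mut) < 2:
        warnings.warn("a group has <2 samples; p-value set to missing")
        return es, float("nan")
    return es, _wilcoxon_p(wt, mut)


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (NaNs propagated)."""
    p = np.asarray(pvals, dtype=float)
    adj = np.full_like(p, np.nan)
    ok = ~np.isnan(p)
    if ok.any():
        adj[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return adj


def build_interaction_table(
    norm: PseudobulkTensor,
    pairs: pd.DataFrame,
    groups: pd.Series,
    fdr_threshold: float = 0.05,
    es_threshold: float = 0.3,
) -> pd.DataFrame:
    """Score and test every (ligand, receptor, cell A, cell B) record.

    ``pairs`` needs columns ligand, receptor, cell_a, cell_b.  Records whose
    ligand or receptor is absent from the tensor (e.g. removed by gene QC)
    are skipped with a warning.  BH adjustment runs jointly over all records
    tested in this call.  Returns one row per record with per-sample NIS
    columns ``nis_<sample>``, enrichment_score, p_value, fdr, significant.
    """
    if not norm.normalized:
        raise ValueError("build_interaction_table requires a normalized tensor")
    samples = norm.samples
    rows = []
    for rec in pairs.itertuples(index=False):
        if rec.ligand not in norm.values.index or rec.receptor not in norm.values.index:
            warnings.warn(
                f"skipping pair ({rec.ligand}, {rec.receptor}): gene not in tensor"
            )
            continue
        nis = pd.Series(
            {
                s: interaction_score(
                    norm, rec.ligand, rec.cell_a, rec.receptor, rec.cell_b, s
                )
                for s in samples
            }
        )
        es, p = test_group_difference(nis, groups)
        row = {
            "ligand": rec.ligand,
            "receptor": rec.receptor,
            "cell_a": rec.cell_a,
            "cell_b": rec.cell_b,
            "enrichment_score": es,
            "p_value": p,
        }
        row.update({f"nis_{s}": nis[s] for s in samples})
        rows.append(row)
    table = pd.DataFrame(rows)
    if table.empty:
        return table
    table["fdr"] = bh_adjust(table["p_value"].to_numpy())
    table["significant"] = (table["fdr"] < fdr_threshold) & (
        table["enrichment_score"] > es_threshold
    )
    return table


def cross_sample_correlation(
    tensor: PseudobulkTensor,
    pairs: pd.DataFrame,
    cell_a: str,
    cell_b: str,
    samples=None,
) -> pd.Series:
    """Spearman correlation across samples between ligand pseudobulk
    expression in ``cell_a`` and receptor pseudobulk expression in ``cell_b``.

    Computed on the (un-normalized) log2(CPM+1) tensor.  Pairs with fewer
    than three informative samples, or a constant vector, yield NaN.
    """
    samples = list(samples) if samples is not None else tensor.samples
    out = {}
    for rec in pairs.itertuples(index=False):
        key = (rec.ligand, rec.receptor)
        lig = np.array([tensor.expr(rec.ligand, s, cell_a) for s in samples])
        recp = np.array([tensor.expr(rec.receptor, s, cell_b) for s in samples])
        ok = ~(np.isnan(lig) | np.isnan(recp))
        if ok.sum() < 3:
            warnings.warn(f"pair {key}: <3 samples, correlation set missing")
            out[key] = float("nan")
            continue
        if np.all(lig[ok] == lig[ok][0]) or np.all(recp[ok] == recp[ok][0]):
            warnings.warn(f"pair {key}: constant vector, correlation undefined")
            out[key] = float("nan")
            continue
        out[key] = float(stats.spearmanr(lig[ok], recp[ok]).statistic)
    return pd.Series(out, name="spearman_rho", dtype=float)
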