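"""Gene-signature construction, scoring and correlation.

A cluster's signature is the set of its differentially expressed genes
(FDR < 0.05 and log2 fold change > 0.5); the signature score of a bulk
sample is the unweighted mean expression of those genes, optionally divided
by PTPRC (CD45) expression to adjust for overall immune content.  Cell-level
pathway scores use a rank-based Mann-Whitney statistic (the UCell-style
definition re-implemented here): robust to the expression scale because it
only sees within-cell ranks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .interaction import _wilcoxon_p, bh_adjust
from .preprocess import PseudobulkTensor

__all__ = [
    "SignatureDef",
    "de_standin",
    "signature_from_de",
    "signature_score",
    "adjust_by_ptprc",
    "signature_correlation",
    "cell_pathway_score",
    "receptor_score_correlation",
]


@dataclass
class SignatureDef:
    name: str
    genes: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError("signature gene list must be nonempty")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("signature genes must be unique")


def de_standin(
    tensor: PseudobulkTensor, cell_type: str, groups: pd.Series
) -> pd.DataFrame:
    """Simple pseudobulk DE between condition groups for one cell type.

    Per gene: log2FC = mean log2 pseudobulk (WT) - mean (MUT) — a log2 fold
    change because the tensor is log2-scale; Wilcoxon rank-sum p across
    samples; BH FDR.  A plumbing DE feeding signature construction, not a
    mixed-model DE method.
    """
    pop = tensor.population_of[cell_type]
    cols = [
        c for c in tensor.values.columns
        if c[1] == pop and c[2] == cell_type
    ]
    if not cols:
        raise KeyError(f"cell type {cell_type!r} absent from tensor")
    block = tensor.values[cols]
    block.columns = [c[0] for c in cols]  # sample ids
    g = groups.reindex(block.columns)
    wt = block.loc[:, (g == "WT").to_numpy()]
    mut = block.loc[:, (g == "MUT").to_numpy()]
    log2fc = wt.mean(axis=1) - mut.mean(axis=1)
    pvals = np.array([
        _wilcoxon_p(wt.loc[gene].to_numpy(float), mut.loc[gene].to_numpy(float))
        for gene in block.index
    ])
    return pd.DataFrame(
        {"gene": block.index, "log2fc": log2fc.to_numpy(), "p": pvals,
         "fdr": bh_adjust(pvals)}
    ).reset_index(drop=True)


def signature_from_de(
    de: pd.DataFrame,
    name: str,
    fdr_threshold: float = 0.05,
    lfc_threshold: float = 0.5,
    max_genes: int | None = None,
) -> SignatureDef:
    """Genes passing FDR < 0.05 and log2FC > 0.5, ranked by effect size.

    ``max_genes`` optionally caps the list (off by default: the thresholds
    themselves define "top").
    """
    hits = de[(de["fdr"] < fdr_threshold) & (de["log2fc"] > lfc_threshold)]
    hits = hits.sort_values("log2fc", ascending=False)
    genes = list(hits["gene"])
    if max_genes is not None:
        genes = genes[:max_genes]
    return SignatureDef(name=name, genes=genes)


def signature_score(expr: pd.DataFrame, sig: SignatureDef) -> pd.Series:
    """Unweighted mean expression of the signature genes, per sample.

    ``expr`` is genes x samples on whatever scale the input carries.
    Signature genes missing from the matrix are dropped with a warning.
    """
    present = [g for g in sig.genes if g in expr.index]
    missing = set(sig.genes) - set(present)
    if missing:
        warnings.warn(f"signature {sig.name!r}: dropping missing genes {sorted(missing)}")
    if not present:
        raise KeyError(f"no signature genes of {sig.name!r} present in matrix")
    return expr.loc[present].mean(axis=0).rename(sig.name)


def adjust_by_ptprc(scores: pd.Series, ptprc: pd.Series) -> pd.Series:
    """CD45 adjustment: score / PTPRC expression; PTPRC <= 0 -> missing."""
    ptprc = ptprc.reindex(scores.index)
    bad = ~(ptprc > 0)
    if bad.any():
        warnings.warn(
            f"{int(bad.sum())} samples with PTPRC <= 0; adjusted score set missing"
        )
    out = scores / ptprc.where(~bad)
    return out.rename(f"{scores.name}_adj" if scores.name else None)


def signature_correlation(scores_a: pd.Series, scores_b: pd.Series) -> float:
    """Pearson correlation of two score vectors across shared samples."""
    df = pd.concat([scores_a, scores_b], axis=1).dropna()
    if len(df) < 3:
        warnings.warn("fewer than 3 samples; correlation set missing")
        return float("nan")
    return float(stats.pearsonr(df.iloc[:, 0], df.iloc[:, 1]).statistic)


def cell_pathway_score(
    expr: pd.DataFrame, gene_set, r_max: int = 1500
) -> pd.Series:
    """Rank-based per-cell gene-set score in [0, 1].

    Per cell, all genes are ranked by decreasing expression (ties averaged),
    ranks capped at ``r_max``; U is the Mann-Whitney statistic of the set's
    capped ranks and the score is ``1 - U / U_max`` with
    ``U_max = n_set * r_max - n_set (n_set + 1) / 2``, so a set occupying
    the top ranks scores exactly 1 and a set entirely at or beyond the cap
    scores exactly 0.  Depending only on within-cell ranks, the score is
    invariant to any monotone transform of a cell's expression.
    """
    gene_set = list(gene_set)
    missing = [g for g in gene_set if g not in expr.index]
    if missing:
        raise KeyError(f"gene set members absent from matrix: {missing}")
    n_set = len(gene_set)
    set_pos = expr.index.get_indexer(gene_set)
    vals = expr.to_numpy(dtype=float)
    u_max = n_set * r_max - n_set * (n_set + 1) / 2.0
    scores = np.empty(expr.shape[1])
    for j in range(expr.shape[1]):
        ranks = stats.rankdata(-vals[:, j], method="average")
        capped = np.minimum(ranks[set_pos], r_max)
        u = capped.sum() - n_set * (n_set + 1) / 2.0
        scores[j] = 1.0 - u / u_max
    return pd.Series(scores, index=expr.columns, name="pathway_score")


def receptor_score_correlation(scores: pd.Series, receptor_expr: pd.Series) -> float:
    """Pearson correlation over cells between a pathway score and the
    normalized expression of its paired receptor."""
    df = pd.concat([scores, receptor_expr], axis=1).dropna()
    if len(df) < 3:
        warnings.warn("fewer than 3 cells; correlation set missing")
        return float("nan")
    return float(stats.pearsonr(df.iloc[:, 0], df.iloc[:, 1]).statistic)
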