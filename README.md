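# tmescope

Statistics for the glioblastoma tumor microenvironment, built around three
questions that recur when comparing IDH-wild-type glioblastoma with
IDH-mutant glioma at single-cell and spatial resolution:

1. **Which ligand-receptor interactions between cell clusters distinguish
   the two tumor types?**  Raw counts are aggregated to per-sample
   pseudobulk (log2(CPM+1) per gene × cell type), min-max normalized across
   the cell types of each population (myeloid / tumor / T), and a pair's
   *normalized interaction score* in sample *i* is

   NIS = f(x_ligand, cell A) · f(x_receptor, cell B),  with
   f(x_gijk) = (x_gijk − min_l x_gijl) / (max_l x_gijl − min_l x_gijl),

   so only cell-type-specific expression scores highly.  Per record a
   two-sided Wilcoxon rank-sum test compares NIS between condition groups,
   the enrichment score is mean(NIS | WT) − mean(NIS | MUT), p-values are
   Benjamini-Hochberg adjusted jointly, and records with FDR < 0.05 and
   enrichment score > 0.3 are called significant.

2. **Which genes change along a differentiation trajectory?**  Expression
   along pseudotime t ∈ [0,1] is modeled on a cubic B-spline basis in three
   hierarchies: population coefficients β ∈ R^N; per-sample coefficients
   a_s = β + u_s with u_s ~ N(0, τI); observed cells
   e_cs = Σ_i φ_i(t_cs) a_is + ε_cs, ε ~ N(0, σ_s²).  Parameters are fit by
   EM (monotone marginal likelihood, closed-form M-step, knots 0–30 chosen
   by BIC), the null β = 0 is tested by permuting pseudotime within each
   sample and refitting (p = fraction of permuted log-likelihoods above the
   observed), genes with BH-adjusted p < 0.05 are trajectory-differential,
   and their fitted curves (resolution 1000) are grouped by k-means.

3. **What happens around necrosis?**  Spatial spots are stratified into 10
   equal-count distance regions from the necrotic mask; a cell type's
   infiltration profile is the per-region fraction of spots whose
   deconvolution weight exceeds the global median.  Ligand-receptor coupling
   is measured by regressing spot receptor expression on the *niche-ligand*
   value (mean ligand over the 20 nearest neighboring spots, self excluded)
   and reporting adjusted R² = 1 − (1−R²)(n−1)/(n−2), separately for the
   perinecrotic half (50% of non-necrotic spots closest to necrosis) and the
   distant rest.

A signatures module scores bulk samples by mean expression of
differentially expressed gene sets (optionally divided by *PTPRC*/CD45) and
cells by a rank-based Mann-Whitney gene-set score, and a synthetic-data
module generates cohorts, pseudotime expression and spot lattices with
known planted truth so every stage is testable without patient data.

## Worked example

```python
import tmescope as tm
import pandas as pd

pair = tm.PlantedPair("G0001", "G0002", "myeloid_1", "tumor_1",
                      group="WT", multiplier=8.0)
cohort = tm.simulate_cohort(tm.CohortConfig(planted_pairs=[pair], seed=0))
cohort = tm.filter_genes(tm.filter_cells(cohort, min_genes=1, min_umi=1))
norm = tm.minmax_normalize(tm.pseudobulk(cohort))
pairs = pd.DataFrame({"ligand": ["G0001"], "receptor": ["G0002"],
                      "cell_a": ["myeloid_1"], "cell_b": ["tumor_1"]})
groups = cohort.obs.drop_duplicates("sample").set_index("sample")["condition"]
table = tm.build_interaction_table(norm, pairs, groups)
print(table[["enrichment_score", "p_value", "fdr"]].round(4).to_string(index=False))
```

prints

```
 enrichment_score  p_value    fdr
              1.0   0.0013 0.0013
```

At multiplier 8 the planted ligand and receptor are the top-expressing cell
types in every WT sample and never in the MUT samples, so NIS is 1 vs 0 in
all twelve samples and the enrichment score is exactly 1.  The p-value is
the tie-corrected normal approximation (the six MUT scores tie at zero);
with a single tested record the BH adjustment leaves it unchanged.  The
same pipeline runs from a shell: `tmescope simulate-cohort`,
`tmescope interaction`, `tmescope trajectory`, `tmescope spatial` (see
`--help` on each).

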