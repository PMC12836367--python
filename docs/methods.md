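# Methods

This note records the models behind `tmescope`, the conventions chosen
where a design was genuinely open, and what the synthetic-data generators
do and do not emulate.

## Pseudobulk and QC

Cells are kept when they reach both inclusive thresholds: ≥ 500 detected
genes and ≥ 750 total UMI ("minimum threshold" is read as the smallest
admissible value).  Genes detected in fewer than 0.1% of cells are removed,
with the fraction computed on the post-cell-filter matrix (the two rules
apply sequentially in that order).  Cell-level normalization is
ln(1 + 10⁴·count/total) — the ecosystem default scale factor — and is used
only for cell-level scoring.  Pseudobulk sums raw counts per (sample,
cluster), converts to CPM and takes log2(CPM+1); clusters with fewer than 3
cells in a sample (configurable) or zero totals are dropped from that
sample because a near-empty cluster yields a degenerate column.

## Normalized interaction score

Min-max normalization runs per gene across the cell types of one
population within one sample.  A gene constant across cell types
(max = min) normalizes to 0 everywhere: such a gene carries no
cell-type-specific signal, so it cannot drive an interaction.  The
Wilcoxon rank-sum test uses the exact distribution when the combined
sample count is ≤ 20 and there are no ties, otherwise the normal
approximation with tie and continuity correction.  The enrichment score is
oriented WT − MUT (positive = glioblastoma-enriched).  The BH family is
all (pair, cell-type-pair) records tested in one call; the adjustment
scope is deliberately explicit because different scopes change what
"FDR < 0.05" means.

Operating characteristics at the default cohort conditions (6 samples per
group, 3 cell types per population, 200 pairs): the null significant
fraction is ~0 (the ES > 0.3 requirement on top of FDR is very
conservative).  Note that with 6 vs 6 samples the exact two-sided rank-sum
p-value cannot fall below 2/C(12,6) ≈ 0.0022, so no single record can clear
a joint BH adjustment over hundreds of records; detecting individual pairs
at FDR level requires either larger cohorts or a smaller test family.

## Trajectory model

For one gene, with B-spline basis φ₁..φ_N (cubic by default; the degree is
a convention, not an estimate) and interior knots at uniform quantiles of
pseudotime:

* population level: β ∈ R^N (intercept-only design x_s = 1; general design
  matrices are accepted but exercised only in the intercept configuration);
* sample level: a_s = β + u_s, u_s ~ N(0, τ I_N).  τ is a scalar
  (isotropic) variance — the minimal structure consistent with one random
  deviation per basis coefficient per sample;
* cell level: e_cs = φ(t_cs)ᵀ a_s + ε_cs, ε ~ N(0, σ_s²).

EM: the E-step is the Gaussian posterior of a_s per sample; the M-step
updates β (mean of posterior means), τ (mean squared posterior deviation
plus posterior variance) and σ_s² in closed form, so the marginal
log-likelihood is non-decreasing — asserted in the tests on every fit.
All computations run off per-sample sufficient statistics (ΦᵀΦ, Φᵀe, eᵀe),
making an EM iteration O(N³) regardless of cell count.  Convergence is an
absolute log-likelihood improvement < 1 (the stated cutoff interpreted as
absolute change), capped at 100 iterations.  The marginal likelihood uses
the Woodbury identity and the matrix determinant lemma, so nothing larger
than N × N is ever factorized.  τ is floored at 10⁻¹² to keep posteriors
defined; `fix_tau=0` collapses the model to pooled GLS for the degenerate
case.  Singular normal equations fall back to a ridge-stabilized solve
with a warning.

Knot selection minimizes BIC = −2·loglik + k·ln(n_cells) with
k = N + 1 + S (β, τ, per-sample σ); cells, not samples, supply the sample
size — the observations are cells.  Ties go to fewer knots.  The selected
basis is reused for all permutation replicates so replicate likelihoods
are comparable.

**Permutation null.**  Each replicate permutes the pseudotime order of the
cells within each sample and refits; p is the fraction of replicate
log-likelihoods above the observed one (denominator = completed
replicates; failures are dropped with a warning above 10%).  Pure
permutation makes the replicate likelihoods exchangeable with the observed
one under the null, so null p-values are uniform — verified by KS test
over 200 null genes.  A variant that additionally bootstraps cells within
samples before permuting is available (`scheme="permute+bootstrap"`), but
measurement shows it shifts the null log-likelihood distribution (KS
statistic ≈ 0.4 against uniform), so it is not the default.  The replicate
count defaults to 100.

**Calibration conditions.**  The recovery benchmark uses S = 4 samples,
2000 cells, N = 7, σ = 0.3, τ = 0.05.  With S = 4 the fixed effect carries
an irreducible error floor E‖β̂ − β‖² ≈ Nτ/S from averaging four random
sample deviations, so the benchmark simulates strongly
trajectory-differential genes (curve amplitude 3 on the standardized SD
scale, ‖β‖ ≈ 2.5) and averages the relative L2 error over 16 genes; this
makes the measured error reflect the estimator rather than signal
weakness, and was fixed from this power analysis before measurement.
Power is evaluated at curve amplitude 1.0 (a gene traversing one standard
deviation), where the permutation test is essentially always significant
at 2000 cells.

Expression is standardized per gene (zero mean, unit variance) before
fitting in the driver, extending the clustering convention to fitting so
the null "flat at zero" is meaningful; fits against known simulated truth
run unstandardized.  Trajectory-differential genes (BH-adjusted p < 0.05)
are clustered by k-means (fixed random state, 10 restarts) on their fitted
curves evaluated on a 1000-point grid; a cluster's pattern is the mean
curve of its genes.

## Spatial statistics

Distance to necrosis is the minimum Euclidean distance to any necrotic
spot, on the coordinates as given (no unit conversion).  Strata are
equal-count, not equal-width: equal-count deciles cannot be empty on
irregular geometries.  Sorting is by (distance, spot id), the id breaking
ties deterministically; the same convention puts the ceiling half of
non-necrotic spots into the perinecrotic region.  "High infiltration" is
strictly greater than the median weight over all non-necrotic spots.
General expression smoothing averages a spot with its k = 6 nearest
neighbors (a hex-like neighborhood, interpreted as k-NN since grid
adjacency is geometry-dependent); the niche-ligand value excludes the spot
itself (k = 20) so it measures the microenvironment, not the spot.  The
niche is computed over non-necrotic spots.  Adjusted R² uses the two-
parameter simple-regression correction (n − 1)/(n − 2) and is undefined
(NaN) below n = 3 or for a constant predictor.

## Signatures

A cluster signature is every gene passing FDR < 0.05 and log2FC > 0.5 in a
supplied DE table ("top" is defined by the thresholds; an optional cap
exists but is off).  The plumbing DE stand-in computes log2FC as the
difference of group means of log2 pseudobulk with a rank-sum p per gene —
it feeds the signature schema and is not a mixed-model DE method.  Scores
are unweighted means on whatever scale the input matrix carries
(documented rather than forced, since the bulk input's transform is the
caller's choice).  The cell-level pathway score ranks all genes within a
cell (ties averaged), caps ranks at r_max = 1500, and maps the gene set's
Mann-Whitney U to 1 − U/U_max with U_max = n·r_max − n(n+1)/2, a
normalization that makes the score span exactly [0, 1] (top-ranked set →
1, fully capped set → 0).

## Synthetic data

`simulate_cohort` draws negative-binomial (gamma-Poisson) counts — the
standard overdispersed scRNA count model — with per-gene baselines
(Gamma-distributed around mean 0.5 counts/cell), lognormal cell-type
specificity (log-sd 0.5), Dirichlet cluster proportions per sample, and
two condition groups of 6 samples by default.  A planted pair multiplies
the ligand mean in cell type A and the receptor mean in cell type B in one
group only.  `simulate_trajectory` draws from the trajectory model itself
with uniform pseudotime (pseudotime reconstruction is out of scope, so any
ordering suffices); null genes are structure-free (β = 0 *and* no random
effect), since a gene with sample-level pseudotime structure is not null
for a test of trajectory dependence.  `simulate_spatial` uses a square
unit lattice (the hexagonal layout of real spot arrays changes nothing for
Euclidean-distance statistics), a central necrotic disk, weights
∝ exp(−d/λ) per cell type (negative λ grows with distance, ∞ is flat) with
lognormal noise (log-sd 0.1) renormalized to the simplex, a smooth
two-wave ligand field, and receptor = slope × niche-ligand + noise inside
the coupling region, using the same niche definition as the analysis so
the theoretical R² = s²·var(niche)/(s²·var(niche) + σ²) is exact up to
sampling noise.

None of the generators emulate gene-gene co-expression networks, batch
effects, ambient RNA, doublets, or tissue histology; passing tests
demonstrate that the statistics recover what the models plant, not that
the models capture every property of patient data.

## Problem sizes

Replicated experiments run at: 100 cohorts × (3600 cells × 250 genes) for
interaction calibration; 200 null + 20 signal genes × 101 EM fits at 2000
cells for trajectory calibration; 16 genes for recovery; 100 spot grids of
40 × 40 for spatial recovery.  The reproducibility script uses 50
replicates per experiment; all quantities it reports are computed at run
time from fresh simulations.
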