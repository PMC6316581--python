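# Methods

## Scientific setting

Papillary thyroid carcinoma (PTC) transcriptomes separate along two axes:
a driver axis (BRAF-V600E-like versus RAS-like expression programs) and an
immune axis (the degree of leukocyte infiltration and cytolytic activity).
`ptcnmf` models a bulk expression matrix `V` (genes x samples, nonnegative)
as a mixture of a small number of nonnegative *metagene signatures*:

    V ~ W H,   W >= 0 (genes x k),   H >= 0 (k x samples)

With k = 3 the signatures align with a RAS program, an immune program and a
BRAF program. Hierarchical clustering of the per-sample signature activities
yields four clusters — RAS-IR, RAS-ID, BRAF-IR, BRAF-ID (IR =
immunoreactive, ID = immunodeficient, i.e. high/low immune-signature within
each driver side) — with the fixed naming NMF1=RAS-IR, NMF2=RAS-ID,
NMF3=BRAF-IR, NMF4=BRAF-ID. The BRAF-IR cluster carries an elevated
recurrence risk, which the clinical module quantifies.

## Factorization

The solver minimises the generalized Kullback–Leibler divergence

    D(V || WH) = sum_ij [ V_ij log(V_ij / (WH)_ij) - V_ij + (WH)_ij ]

by the classical multiplicative updates, which never increase the objective.
Initialisation is uniform(0,1) scaled by mean(V), seeded; updates stop at
`max_iter` or when the relative divergence decrease over a 10-iteration
window falls below `tol`. An epsilon of 1e-12 guards divisions and logs.
Log-scale inputs are shifted so their minimum is zero before factorization
(generalized KL requires nonnegative data). After convergence the basis
columns are rescaled to unit L1 norm with the inverse scaling applied to the
activity rows, removing the diagonal ambiguity so output is canonical.

Key parameters: `k` (signature count), `seed`, `max_iter` (default 1000 for
final fits, 300–500 for consensus restarts), `tol` (1e-6 final, 1e-5
consensus). A Frobenius objective is deliberately not offered; for
log-scale RNA abundance the KL objective weights genes by magnitude in the
way the consensus methodology this module follows expects.

## Rank selection by consensus stability

For each candidate rank, `n_runs` seeded restarts each assign every sample
to its maximal-activity signature (ties to the lowest index). The consensus
matrix is the run-average of the co-assignment indicator; the cophenetic
correlation between the consensus dissimilarity (1 − C) and the cophenetic
distances of its average-linkage dendrogram quantifies how block-like the
consensus is (1 = perfectly reproducible clustering).

`select_rank` returns the first rank k whose coefficient drops by at least
`drop_threshold` at k+1 while k itself is within twice the threshold of the
running maximum; if no drop qualifies, the arg-max rank is returned with a
warning. The default threshold of 0.01 sits between the two empirical
scales the survey produces on cohorts with planted structure: fluctuations
of a few thousandths at stable ranks versus breaks of 0.02–0.05 past the
true rank. A first-drop rule rather than a last-drop rule is used because
cophenetic curves decay gradually beyond the true rank and late drops of
similar size would otherwise pull the selection toward over-complete
factorizations — on data with four activity clusters, a rank-4 consensus
remains fairly stable even when the gene-space structure is rank 3.

## Cluster naming and projection

Samples are clustered on per-signature z-scored activities with Ward
linkage on Euclidean distance, cut at four clusters (the linkage method is
configurable; Ward gives compact, deterministic cuts).
Signature roles are resolved by driver contrast: the RAS signature maximises
mean activity in RAS-like minus BRAF-like samples, the BRAF signature the
reverse, the remainder is Immune and is cross-checked against an immune
marker score (CYT by default) — a mismatch logs a warning rather than
failing, since the contrast is the primary evidence. Cluster labels follow
a rank-based 2/2 split of the four clusters by mean (RAS − BRAF) activity;
within each side the higher mean immune activity is IR. Ties at either
boundary raise errors with diagnostics rather than being broken silently.

External cohorts are classified by metagene projection: after aligning
genes to the basis (minimum overlap 50% of basis genes and 200 genes,
both configurable), activities are `pinv(W) @ V` with negative entries
clamped to zero; an NNLS mode (`mode='nnls'`) solves the nonnegativity
constraint exactly instead. Clamping is the default because it is cheap,
transparent, and identical to NNLS whenever the unconstrained solution is
already nonnegative (the usual case at realistic overlap).

## Immune profiling

* CYT score: `sqrt((GZMA + c)(PRF1 + c))` on linear expression, offset
  c = 0.01 so zero-expression samples keep a defined, floored score.
* Signature scores: mean per-gene z-score of a gene set on log-scale
  expression. This is a transparent surrogate for single-sample enrichment
  scores; it is reported under its own name and is not a reimplementation
  of any published scorer.
* Cell fractions: nonnegative least squares of each sample against a
  genes x cell-types reference profile on their shared genes (minimum 50).
  The sample is rescaled to the reference's mean column sum, making the
  estimate invariant to library size; fractions are renormalised to sum to
  one and the residual norm is reported. The reference is assumed to be on
  a common per-column scale. This is a deliberately simple linear
  deconvolution; outputs are relative abundances, not calibrated counts.
* Pre-ranked enrichment: weighted Kolmogorov–Smirnov running sum (weight
  exponent 1) over a gene ranking; ES is the maximum-deviation value. The
  permutation p-value shuffles set membership and uses the plus-one
  estimator, so p >= 1/(n_perm+1). A set covering the entire ranking is
  compared against the uniform walk and scores 0.
* Per-cluster feature summaries use one-way ANOVA with a p < 0.05 display
  flag; constant features score F = 0.

## Clinical association

The 2x2 odds ratio is the cross-product ratio with the Wald interval
`exp(log OR ± z sqrt(1/a+1/b+1/c+1/d))`; an optional Haldane correction
adds 0.5 to all cells only when a cell is zero. Logistic models are
maximum-likelihood fits (statsmodels Newton/IRLS) with divergence beyond
|beta| > 15 reported as separation. Chi-square tests are Pearson without
continuity correction; Fisher's exact test is reserved for 2x2 tables (the
package logs the expected-count rule of thumb). Kaplan–Meier and log-rank
come from lifelines; Cox proportional hazards from statsmodels PHReg with
Efron tie handling by default and Breslow available.

The risk-factor table builder dichotomizes age (>= 55), sex, histologic
variant (tall cell / columnar / hobnail = aggressive), extrathyroidal
extension, pT3-4, pN1, driver class (BRAF-like), mutation burden (> 11) and
cluster (NMF3 vs rest), computes univariate ORs per variable on its
complete cases, and carries variables with univariate p < 0.25 into a
single multivariate logistic model — odds ratios, not hazard ratios, since
the model is binomial logistic.

## Synthetic cohorts

The generator plants the full structure the pipeline is meant to recover:

* Basis: each signature owns a disjoint dominant gene block
  (`signature_sparsity`, default 5% of genes) with gamma(2,1)+0.5 loadings
  and a small gamma background elsewhere. Named immune markers (GZMA, PRF1,
  CD274, CTLA4, CCL19, CCL21) are embedded in the immune block.
* Activities: four cluster archetypes — (RAS, Immune, BRAF) means of
  (10,8,1), (10,1,1), (1,8,10), (1,1,10) — times per-signature gamma jitter
  with CV `activity_dispersion` (default 1/3, a realistic within-cluster
  spread for bulk tumour signature activity; exact-recovery tests use
  tighter values).
* Expression: `W @ H` times multiplicative log-normal noise
  `exp(N(0, noise_sd^2))`, preserving nonnegativity.
* Cluster proportions default to (0.13, 0.19, 0.32, 0.36), the observed
  four-cluster split of the cohort the model was developed on.
* Clinical: recurrence is Bernoulli with per-cluster rates, default
  (0.058, 0.058, 0.131, 0.058) — elevated in BRAF-IR. Event times are
  exponential with cluster-dependent scale (months); non-recurrent samples
  are censored uniformly over a 120-month window, and a `censoring_rate`
  fraction of recurrent samples can be administratively censored (clearing
  the survival `event` flag but not the `recurrence` status). Covariates
  (age, sex, variant, ETE, pN, mutation burden) follow cluster-linked
  probabilities so the table builder has realistic structure to find.
* External features: leukocyte fraction, tumour purity and TCR richness are
  planted with configurable correlations (default 0.8, −0.7, 0.73) to the
  true immune activity.

What the generator does **not** emulate: gene-gene correlation beyond the
three planted programs, count noise/overdispersion of raw RNA-seq,
batch effects, partial-volume mixtures between clusters, and any genuinely
continuous immune gradient (IR/ID are discrete archetypes with
within-cluster spread). Passing tests therefore show the pipeline recovers
the structure it assumes when that structure is present at realistic noise;
they do not show the four-cluster model is the right description of any
particular real cohort.

## Problem sizes and numerical choices

Cohort-scale experiments use 2000 genes x 400 samples at noise_sd 0.2,
rank surveys over k = 2..6 with 10 restarts per rank (max_iter 300,
tol 1e-5), and final fits at max_iter 1000, tol 1e-6; simulator calibration
uses 5000 samples, and estimator-recovery checks n = 2000. These sizes give
stable, reproducible statistics at desk scale. Degenerate inputs are
handled explicitly: constant consensus dissimilarity returns a cophenetic
coefficient of 1 by convention (logged); zero-variance features correlate
as NaN with a warning; assignment ties break to the lowest signature index
(logged); labeling ties are errors.

## Known limitations

* KL multiplicative updates converge to local optima; consensus across
  restarts measures, but does not remove, that dependence.
* The pinv-then-clamp projection is not the exact nonnegative solution;
  use `mode='nnls'` when negative loadings are material.
* The mean-z signature score and NNLS fractions are simple surrogates for
  the established single-sample enrichment and SVR deconvolution tools and
  should not be compared numerically against their outputs.
* The multivariate models assume complete cases on the selected covariates;
  no imputation is performed (counts are logged).
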