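# Methods

## Pseudotime projection model

A bulk cohort **B** (genes × samples, log-scale expression) is mapped
onto a single-cell reference trajectory **R** whose cells carry a known
pseudotime *P* ∈ [0, 100]. Per reference:

1. **Gene alignment.** Bulk and reference are restricted to their
   shared genes (exact symbol matching, sorted). At least two shared
   genes are required; in practice the 32-gene EMT marker panel plus
   whatever else the platforms share.
2. **Purity adjustment (optional).** Each bulk gene is replaced by the
   residuals of a univariate least-squares regression on tumour purity,
   re-centred at the gene's mean. The output is exactly uncorrelated
   with purity, removing the linear component of stromal/immune
   contamination. This happens before merging so the reference is
   untouched.
3. **Batch correction.** The merged matrix is corrected with parametric
   empirical-Bayes location/scale adjustment (ComBat), treating
   {bulk, reference} as the two batches. Per gene the data are
   standardised after a least-squares fit of batch effects; per-batch
   gene-wise means and variances are shrunk toward batch-level moments
   under normal / inverse-gamma priors and divided out. The correction
   is delegated to scanpy's ComBat port, which we verified against
   sva::ComBat in R (maximum discrepancy 1.5e-3 on a 20-gene fixture).
   Shrinkage is genuine: a pure gene-wise batch shift is removed only up
   to the empirical-Bayes residual (~2% of the shift), not exactly.
   Genes with zero within-batch variance cannot be standardised and are
   mean-equalised only; if fewer than three genes are eligible for
   empirical Bayes (across-gene priors undefined), a plain
   location/scale equalisation is used instead.
4. **Embedding.** PCA on the corrected merged matrix
   (`n_components = 25` by default — enough to span the trajectory
   manifold while discarding noise directions; genes with numerically
   zero variance are dropped first). Component signs are fixed by
   making each component's largest-magnitude gene loading positive, so
   the embedding is fully deterministic.
5. **Transfer.** Each bulk sample receives the arithmetic mean
   pseudotime of its `k = 10` nearest reference cells (Euclidean
   distance in the embedding, brute-force search; distance ties resolve
   by cell index). Every estimate is a convex combination of reference
   pseudotimes and therefore stays in [0, 100]. Samples are mapped
   independently of one another given the embedding.

The consensus over several references is the unweighted row mean. `k`
and the dimensionality are exposed because neither has a canonical
value; 10 neighbours is small relative to typical reference sizes
(hundreds of cells) and 25 components generalises the tissue-specific
setting to the consensus pipeline.

## EMT score

Per gene, a z-score across the cohort (constant genes map to 0, which
makes the degenerate all-constant matrix score 0 rather than NaN); the
sample score is mean mesenchymal *z* minus mean epithelial *z*. The
score is invariant under any gene-wise affine transform of expression.
The marker panel is 4 epithelial + 16 mesenchymal + 12 hybrid genes and
can be replaced by a two-column TSV.

## Segmentation

Samples are sorted by pseudotime. A lasso of pseudotime on the 32
marker genes (10-fold CV, one-standard-error rule) picks the genes that
track the trajectory; if nothing survives (e.g. constant pseudotime)
all markers are used with a warning. A Gaussian-emission HMM with
diagonal covariance is fitted on the selected sub-matrix by EM, with 5
restarts seeded deterministically from the user seed and the best
log-likelihood kept (restarts guard against EM local optima; 2 suffice
in the robustness loop where speed matters). Decoding is by argmax of
the smoothed posteriors — posterior decoding rather than Viterbi so
each sample carries a usable confidence. Hidden states are labelled by
the posterior-weighted mean of each sample's epithelial-minus-
mesenchymal z-score: highest → EPI, lowest → MES, middle → hEMT, ties
broken toward the lower state index. Final labels are invariant to any
permutation of internal state indices. Three states are the default;
`bic_report` scores 2–6 states for users who want to check the choice.

Minimum emission variance is floored at 1e-3 to keep EM stable on
near-degenerate genes.

### Noise robustness

Expression is perturbed with Uniform(−a, +a) jitter and the full
segmentation (marker selection + HMM + labelling) is re-run with the
pseudotime fixed; recorded per repetition are the fraction of samples
keeping their original state and the fraction reassigned. The default
grid spans geometrically from range/50 (the conventional jitter default)
to 2× the data range, so it transfers across expression units. The
robustness loop deliberately does not re-project pseudotime: the
question it answers is how fragile the state boundaries are to
expression noise at a fixed ordering.

## Stability selection

For a pairwise contrast (e.g. MES vs EPI), a stratified 20% holdout is
split off first and never touched during selection. Each of the
`n_iter` iterations draws a stratified `train_frac` resample of the
remaining pool and fits an L1-penalised logistic regression of state
membership on the binary events, with one indicator per tissue entering
unpenalised. The per-feature penalty is implemented by feature
rescaling, which is exact for L1 penalties (penalty weight *w* equals
scaling the feature by 1/*w*); tissue indicators are scaled by 1e3,
making their effective penalty negligible. The penalty strength is
chosen per iteration by stratified 3-fold cross-validation with the
one-standard-error rule (the strongest penalty within one SE of the CV
optimum) — without the 1-SE rule, chance correlations that persist
across overlapping resamples are selected far too often under the null.
Events with non-zero coefficients are recorded; selection frequency is
the fraction of iterations selecting the event, thresholded at 0.8
(stable set) and 0.5 (extended set). The final model refits the stable
events plus tissue with a weak L2 penalty on the pool and is scored by
ROC AUC on the holdout; with an empty stable set the AUC is reported as
0.5 (uninformative) with a warning.

Both states must have ≥ 20 samples — below that, resample stratification
and the holdout split become unreliable.

## Closed-form estimators

- **Cancer cell fraction**: CCF = VAF · (2 + ρ·(CN − 2)) / ρ, i.e.
  VAF · (2/ρ + CN − 2) — the expected mutant-cell fraction for a
  heterozygous mutation after correcting VAF for normal-cell dilution
  and local copy number CN. It is linear in VAF and decreasing in
  purity for every CN. Values above 1 are capped and flagged (they
  indicate multi-copy mutations or inconsistent inputs). The
  alternative reading of the formula in which purity cancels,
  CCF = CN · VAF, is available via `purity_scaled=False`.
- **Hypoxia score**: number of signature genes above the cohort median
  minus number below; ties contribute 0. Signature gene lists are
  caller-supplied.
- **Hypergeometric enrichment**: P(X ≥ observed) computed through the
  log survival function so tails around 1e-25 do not underflow; tests
  verify against exact rational summation.

## Synthetic-data generator

The generator defines the study conditions under which the pipeline is
validated. Cells and tumours sit at a latent t ~ Uniform[0, 100].
Epithelial markers follow decreasing sigmoids of t, mesenchymal markers
increasing sigmoids (midpoints U(40, 60), slopes U(0.10, 0.20) per gene,
so markers are informative but not collinear), hybrid markers a Gaussian
bump at t = 50 (width U(10, 18)); amplitudes are 3 log-units over a
baseline of 2, so the three terciles of t separate cleanly at the
default noise sd of 0.3. Non-marker genes are t-independent at gene-
specific baselines U(2, 8). Ground-truth macro-states are the terciles
of t (EPI < 33.3 ≤ hEMT < 66.7 ≤ MES).

Bulk samples mix the tumour profile at their latent t with a fixed
fibroblast-like stromal profile, weighted by purity ~ U(0.6, 1.0):
stromal mesenchymal markers sit at baseline + 1.5× amplitude — above
the tumour MES extreme, as cancer-associated fibroblasts express
VIM/FN1/ECM genes well beyond carcinoma cells — hybrid ECM genes at
+0.8× amplitude, epithelial genes at baseline, and non-marker genes
carry N(0, 0.5) stromal offsets. This makes contamination a genuine
confound: the raw consensus pseudotime correlates with purity at
|r| ≈ 0.05–0.12, which purity adjustment reduces below 0.05. Platform
batch effects are gene-wise offsets ~ N(0, `batch_shift`) applied to
the bulk side (a scalar shift would make ComBat's gene-wise machinery
untestable). Time courses draw t ~ Normal(μ_j, σ) per time point,
clipped to [0, 100], without stromal mixing (cell-line experiments).

Genomic events are Bernoulli(0.1) background; planted events have those
odds multiplied by the effect size within their associated state;
optional decoy events vary by tissue only (rates U(0.02, 0.35)), which
the tissue-adjusted lasso must reject.

All generators are pure functions of (config, seed) via independent
seed-sequence streams, so the reference and bulk cohort of one config
share identical gene response curves while drawing independent noise.

What the generator does **not** model: count noise, dropout, library
size variation, multiple stromal cell types, copy-number-driven
expression, or tissue-specific baseline expression. Passing tests
therefore demonstrate the statistical machinery recovers planted
structure under Gaussian log-scale noise with a single contaminant —
not that real cohorts meet these assumptions; on real data the
practitioner should check purity estimates, reference-cohort platform
compatibility and marker coverage first.

## Problem sizes and numerical choices

Validation cohorts are 500 reference cells with 300–600 bulk samples,
200 genes, 100 genomic events with 5 planted at odds ratio 10, 200
stability iterations and 10 robustness repetitions per noise level —
large enough for the planted effects to dominate sampling noise while a
full validation run completes in well under a minute. Degenerate inputs
are handled explicitly: constant genes z-score to 0, zero-variance
genes bypass ComBat standardisation and PCA, constant purity makes
adjustment a no-op, constant pseudotime triggers the marker-selection
fallback, and an empty stable event set yields AUC 0.5 rather than a
crash. Consensus validation tolerates 1e-9; HMM transition rows are
checked to sum to 1 at the same tolerance.

## Known limitations

- Pseudotime estimates depend on the cohort through batch correction
  and PCA: adding samples changes the embedding slightly. The
  per-sample k-NN transfer itself is cohort-independent given fixed
  coordinates.
- Gene matching is exact-string on symbols; no alias resolution.
- The hybrid state is treated as a single state; finer sub-states are
  out of scope.
- Stability selection fits pairwise contrasts, not a single multinomial
  model; events associated with a state absent from the contrast are
  invisible to it.
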