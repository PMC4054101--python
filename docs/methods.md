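# Methods

This note documents the models, procedures, and numerical choices behind
`phosresp`, and what the synthetic-data experiments do and do not show.

## Quantification model and normalization

The unit of quantification is the phosphopeptide: a tryptic peptide with
one or more phosphorylated S/T/Y residues, measured as a label-free
chromatographic peak intensity per sample. Intensities span orders of
magnitude and are treated as log-normal.

Two normalizations are applied in a fixed order (asserted via the matrix
provenance record):

1. **Total-intensity scaling.** Each sample column is scaled so all column
   sums equal the grand mean of the original column sums. This is a proxy
   for equal total chromatogram intensity per run; the choice of the common
   constant is irrelevant because step 2 removes it.
2. **Row-mean scaling.** Each peptide row is divided by its mean across
   samples, producing dimensionless fold-over-mean relative intensities
   with row mean exactly 1. Within-peptide ratios between samples are
   preserved exactly.

Log transformation defaults to base 2 (the scale on which correlations and
group tests are computed); natural log is available. Non-positive values
are either rejected or floored at half the matrix's minimum positive value,
by explicit policy. The intensity cutoff filter keeps peptides by maximum
raw intensity across samples, either the top n or a minimum-maximum
threshold; the 1500 default is the count conventionally used for PCA
inputs in this kind of panel, since instrument-specific peak-intensity
cutoffs do not transfer between datasets. Ties in top-n are broken
lexicographically by peptide id.

## Unsupervised classification

PCA runs on the peptide-mean-centered log2 matrix via SVD; components are
ordered by explained variance, and each component is oriented so its
largest-magnitude loading is positive (deterministic sign).

Sample distances are d(i,j) = 1 − τ_b, with Kendall's tie-corrected τ_b
because relative-intensity data contain ties after imputation. d lies in
[0, 2], is symmetric with zero diagonal, and is not a metric (no triangle
inequality is asserted). Hierarchical clustering is complete linkage; the
agglomeration is implemented directly (n ≤ a few hundred samples) so the
tie-break is well-defined: among tied pairs, the pair whose smallest member
labels sort first lexicographically merges first. Merge heights are
non-decreasing by the complete-linkage update. scipy's linkage is used as
an independent cross-check in the test suite, and trees serialize to
Newick.

Differential filtering runs per disease group in two modes:

* `anova_tukey` (default, the stringent rule): one-way ANOVA on log2
  intensities across groups, Bonferroni-corrected over peptides; Tukey HSD
  (Tukey-Kramer for unequal group sizes) pairwise; a peptide passes for a
  group when the corrected ANOVA p and every pairwise Tukey p involving the
  group are below the threshold (default 0.01) and the fold — group mean
  over the mean of all remaining samples on the linear relative scale, or
  its reciprocal for decreases — exceeds the threshold (default 2).
* `ttest_fdr`: per-group-vs-rest Welch t-test with Benjamini-Hochberg
  correction over peptides (default threshold 0.05), same fold rule.

Both modes are exposed because both rules appear in practice; neither is
silently preferred in reports. Tests run on log2 intensities (the scale on
which the variance model is closest to homoskedastic); folds are linear.
Numerical note: Tukey pass/fail decisions compare the studentized-range
q statistic against the exact critical value (one cached `ppf` evaluation
per group/df combination); reported Tukey p-values are interpolated from a
cached survival-function grid with ~1e-4 absolute accuracy, which keeps a
2,000-peptide dataset under half a second rather than ~25 s.

## LOCLO lasso prediction

For each drug, X is the samples × peptides matrix of fold-over-mean
intensities with each peptide column standardized to mean 0, sd 1, and y
the viability scores (each replicate carries its cell line's viability).
The objective is the standard lasso

(1/2n) Σᵢ (yᵢ − β₀ − xᵢᵀB)² + λ Σⱼ |βⱼ|,

with unpenalized intercept (β₀ = mean(y) for centered X) and the null
model exactly at λ ≥ λ_max = maxⱼ |xⱼᵀ(y − ȳ)|/n. The solver is
scikit-learn's coordinate descent, whose objective is identical; the test
suite checks it against an independent grid-refinement minimizer on small
problems.

Per held-out cell line: all of that line's replicates are excluded;
standardization parameters are estimated on the training samples only and
applied to the held-out samples (no leakage). A `paper_mode` flag instead
standardizes over the full matrix at once — the convention of workflows
that normalize X before splitting. λ is selected by 3-fold CV (shuffled folds, seeded)
minimizing mean held-out squared error over a 100-point log grid spanning
[λ_max·1e-3, λ_max]; MSE is the natural loss for a squared-error objective,
ties go to the larger λ, and a one-standard-error rule is available. The
selected-λ refit uses the whole training set (the 18 samples in the 7×3
design). CV-selection plus refit is repeated 20 times with fresh folds;
coefficients and the per-regressor non-null indicator are averaged. The
refit follows a 30-point warm-started path from λ_max down to the selected
λ (tolerance 1e-6), which matches a cold high-precision fit to ~5e-3 in
the coefficients and is an order of magnitude faster on wide matrices;
`lasso_fit` itself is a cold fit at tolerance 1e-8.

Predictions of the averaged model on the held-out samples are z-normalized
together with its training-set predictions; observed viabilities are
z-normalized per drug; Pearson R between predicted and observed uses the
two-sided t transform with n − 2 df, treating replicates as independent
(the convention the sample count implies). If every model collapses to the
null model (e.g. y constant), predictions are constant, R is undefined,
and the result is flagged degenerate rather than asserted.

Fold models pool into a per-drug descriptive model: coefficients and
inclusion frequencies averaged across the folds (zeros included),
membership = selected in at least one fold model, stable excerpt =
pooled frequency > 0.5.

**Known limitation — stability of duplicated markers.** When several
predictors are near-duplicates of one latent signal (as planted markers
sharing a single viability dependence necessarily are: pairwise r ≈ 0.97
at the default slope and noise), the L1 penalty keeps a sparse
representative subset — empirically at most ~3 of 10 such markers are
active at any λ, and the choice is driven by noise alignment, stable
across CV folds and subsamples. Model averaging therefore spreads pooled
inclusion frequencies across the duplicate set (mean fraction above 0.5
≈ 0.45 under the default conditions) instead of pushing every true marker
above 50%. Prediction quality is unaffected; interpretation of inclusion
frequencies on strongly collinear panels should treat the duplicate set,
not the individual peptide, as the unit of stability.

## Marker discovery

Correlations are computed at the replicate level (every sample contributes
one point). Both linear-scale and log2-scale ("semi-log") Pearson R are
reported; semi-log is the ranking axis because intensity–viability
relationships are typically exponential, hence linear in semi-log.
Zero-variance peptides are flagged invalid and excluded from ranking.
Group 1 (resistance) is the top k by R_log, group 2 (sensitivity) the
bottom k (default k = 10), with the |R| ≥ 0.45 qualification applied by
default (a flag disables it for workflows that rank purely by top-k);
ties break by |R| then peptide id. Group sums are
taken over fold-over-mean normalized intensities; the ratio statistic is
sum1/sum2 per sample. "Most resistant/sensitive line" = max/min mean
viability for the drug; folds compare cell-line means of a statistic
between those two lines. Cross-cohort transfer recomputes R for a fixed
marker panel on a second cohort without re-selection, reporting (not
erroring on) missing peptides.

The CLI's `significant_markers` flag is calibrated: with n = 21 the
|R| ≥ 0.45 cut alone passes ~4% of null peptides, so the flag requires at
least one selected peptide to survive Benjamini-Hochberg correction of the
correlation p-values across all peptides.

## Motif analysis

Windows are 15-mers centered on the phosphosite (1-based positions),
`_`-padded beyond protein termini; the protein database is an explicit
FASTA with exact lookup (no remote extension of short contexts —
deterministic and offline). Motifs are wildcard patterns with exactly one
phosphoacceptor: class ST centers match S or T interchangeably (S/T
kinases do not distinguish them at the motif level), class Y is the single
pY group. `x` matches anything including padding; a residue constraint is
never satisfied by padding, so constraints falling off a terminus correctly
fail. Subset monotonicity holds by construction: a window matching a motif
matches every relaxation of it.

The packaged library (`data/motif_library.tsv`, swappable; results report
the library used) covers common basophilic (xRxSx, xKxSx, xRxxSx, RxRxxSx,
KxRxxSx, …), proline-directed (xSPx, …), acidophilic (SxxE, SxxD, …), and
hydrophobic-directed classes plus pY; its exact composition is a versioned
data file, not a claim of completeness. Aliased patterns (same constraint
set under two names) are deliberately excluded.

Motif-level correlation: peptides passing the per-peptide |R| ≥ 0.45
pre-filter (disablable) and matching a motif contribute their log2
normalized intensities; the per-sample mean profile is correlated with
viability at the replicate level (consistent with the marker module);
motifs rank by |R|, with the match count n reported. Motifs matching zero
peptides are listed separately, and duplicate peptide ids collapse before
averaging.

## Synthetic data generator

The generator is first-class, tested code that defines the study
conditions:

* **Classification design** (defaults): 2,000 peptides; AML, lymphoma,
  myeloma with 3 cell lines each; 6 replicates (54 samples). Baseline
  log-intensities are N(14, 1.5²) (natural log of arbitrary intensity
  units, matching ~10⁶-scale MS intensities). Per disease, a disjoint
  random 5% of peptides is multiplied by the disease fold (default 2) in
  that disease's samples. Each cell line carries a per-peptide log-normal
  offset profile (sd 0.15) — smaller than the disease shifts — giving
  replicates of a line a shared identity. Replicate noise is multiplicative
  with CV 0.2 via the exact log-normal relation σ² = ln(1 + CV²). A config
  flag can blank a uniform fraction of cells to exercise reader-side
  missing-data policies.
* **Drug-response design** (preset): 2,000 peptides; 7 AML lines in
  triplicate (21 samples); viabilities spread evenly over 5–95% of control
  and permuted per drug. Resistance markers follow
  baseline · exp(slope · (v − v̄)) with slope 0.05 per viability point
  (sensitivity markers negate the slope) — the exponential law, centered so
  a handful of markers cannot dominate a sample's total intensity and
  distort total-intensity normalization. Per-line offsets are zero in this
  preset: the design's contract is that non-marker peptides are independent
  of viability, which also makes the null distribution of per-peptide R
  exactly the t null at n = 21. Motif-assigned peptides (10 motifs × 15
  peptides by default, disjoint from markers) share an additive log-scale
  shift per cell line — their motif's latent kinase activity, drawn
  N(0, 0.5) per line, except the designated responsive motif (default
  RxRxxSx, a most-specific pattern so superset-motif peptides cannot dilute
  it) whose activity is 0.02 · (v − v̄), i.e. linked to viability.
* **Protein database**: per peptide, a random 24–40-residue protein and a
  site position such that the window realizes the assigned motif (all
  constrained offsets inside the protein; wildcards uniform over the 20
  amino acids); unassigned peptides get unconstrained S/T/Y sites anywhere,
  so terminal padding arises naturally.

All randomness flows from the config seed through tagged
`default_rng([seed, tag])` streams; identical configs give bit-identical
outputs, and the planted truth (effect sets, markers, motif assignments,
activities) is serialized as JSON next to the data.

What the generator does **not** emulate: missing-not-at-random patterns,
retention-time or batch effects, peptide identification ambiguity,
correlated baseline structure between peptides of one protein, and
realistic residue frequencies in protein sequences (windows are uniform
over amino acids, so chance motif matches are rarer than in real
proteomes). Passing recovery tests on this generator shows the pipeline's
statistics behave as designed under their own assumptions — not that real
cohorts will reach the same correlations.

## Problem sizes in tests and the acceptance script

Recovery experiments run at the study-scale 2,000 peptides except the
LOCLO experiments, where sizes are chosen to keep full runs to minutes on
one CPU: signal recovery uses 1,000 peptides × 20 seeds (10 planted
markers, 20 averaging iterations — recovery is insensitive to the null
peptide count, which only adds unselected columns), and null calibration
uses 200 peptides × 100 seeds with 3 averaging iterations (the null R
distribution does not depend on the averaging depth). The demo subcommand
defaults to the full 2,000-peptide designs and completes in about a
minute.
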