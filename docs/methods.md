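# Methods

This note records the modelling choices behind `radstage`: what each stage
assumes, which parameters matter and why their defaults are what they are,
what the synthetic cohorts do and do not emulate, and the numerical
conventions a reader needs to reproduce or audit the results.

## Radiomic extraction

**Coordinates and spacing.** Volumes are `(slice, row, col)` arrays with
physical voxel spacing in mm.  No resampling is performed; spacing enters
only the shape features.  Masks are inclusive (voxel centers) and must share
the volume's grid exactly.

**Normalization and discretization.** Each volume is min–max scaled to
[0, 1] (a constant volume maps to zeros).  Texture families operate on a
fixed-bin-count discretization of the ROI: N = 2^x gray levels over the
ROI's own [min, max], `level(v) = min(N, floor(N·(v−min)/(max−min)) + 1)`.
Reading the bin parameter as the *exponent* x ∈ 1..8 (so 2–256 gray levels)
is the only reading under which it is a discretization parameter at all;
together with min–max binning it makes every discretized-texture feature
invariant to strictly increasing affine transforms of the raw intensities —
a property the test suite enforces.

**The parameter sweep.** One "kernel" parameter is reused across families
with per-family semantics: offset distance for the co-occurrence matrix,
Chebyshev neighborhood radius for the dependence and gray-tone-difference
matrices.  Run-length and size-zone matrices take no kernel; size-zone also
takes no angle (zones are 26-connected components).  Angles are the four
unique in-plane directions {0°, 45°, 90°, 135°} applied per axial slice —
opposite directions are redundant because the co-occurrence matrix is
symmetrized.  The full default sweep (8 bins × 5 kernels × 4 angles)
yields 4612 records per case:
20 shape + 15·8 first-order + 20·8·5·4 GLCM + 15·8·4 GLRLM + 14·8 GLSZM +
12·8·5 GLDM + 5·8·5 NGTDM.

**Family feature lists.** The per-family lists are trimmed from the
consensus sets to fixed sizes (15/20/15/14/12/5 texture + 20 shape); e.g.
GLRLM omits LongRunHighGrayLevelEmphasis.  The lists are module constants
(`FIRST_ORDER_FEATURES`, `GLCM_FEATURES`, ...), not configuration.

**Conventions.** Population (n-denominator) variance; Pearson kurtosis (not
excess); linear-interpolation percentiles; first-order Entropy/Uniformity
computed on the discretized histogram.  GLDM dependence is the raw count of
equal-level masked neighbors (center excluded); emphasis denominators use
dependence + 1 so isolated voxels are well defined and an alternating
pattern maximizes SmallDependenceEmphasis.  Features whose denominators
vanish (Correlation and the information measures on a degenerate GLCM,
Busyness on a single-level ROI, dispersion statistics on a single voxel,
third-axis lengths of planar masks) are *flagged inoperable* and emitted as
`value = NaN, operable = False`, never as silent non-finite numbers.

**Surface area.** The default surface is a marching-cubes mesh of the mask
(`skimage`), with mesh volume from the divergence theorem.  Voxel-face
counting is available via `surface_method="face"`; it is exact for
rectilinear phantoms (a cube scores the closed-form sphericity
(π/6)^(1/3) ≈ 0.806) but overestimates curved surfaces by roughly 3/2, which
would cap a digitized ball's sphericity near 0.67 — the mesh surface keeps
it above 0.9, which is why mesh is the default.

## Genomic analysis

**Differential expression.** The NB Wald test is intentionally simple: it
keeps the parts of the standard workflow that matter for calibration
(median-of-ratios size factors, NB mean–variance relation, BH adjustment)
and drops empirical-Bayes dispersion shrinkage, outlier replacement and
independent filtering.  Dispersion is method-of-moments per gene,
α̂ = max(0, (Var − μ·E[1/s]) / μ²), averaged across the two groups.  The
Wald statistic is referred to a **t distribution with n₁ + n₀ − 2 df**: the
standard error is estimated from the same small samples, and at cohort
sizes like 10 + 10 a normal reference is visibly anticonservative (≈6.9%
null rejections at α = 0.05 over 2000 genes, versus ≈5.5% inside the
binomial 99% CI with the t reference).  Genes with zero counts in both
groups are skipped and flagged; a group mean of zero is replaced by a 0.5
pseudocount on the normalized scale for fold-change purposes only.  All
p-values are two-sided; `direction` is `up_in_high` iff log2fc > 0, where
"high" is the extra-vesical class.

**DEG intersection.** Genes must be significant (BH-adjusted p < α, default
0.05) in *every* dataset with the *same* direction; the operation is
commutative and associative, and an empty overlap is an empty result, not
an error.

**ssGSEA.** Per sample, genes are ranked by expression descending with
average ranks on ties.  For a set S the score is
Σᵢ [P_in(i) − P_out(i)] over gene positions i, where P_in weights in-set
genes by rank^α (α = 0.25, the algorithm's canonical default — the weighting
is not specified by the problem and 0.25 is the accepted choice) and P_out
is the uniform CDF over out-of-set genes.  Scores are **not** normalized
across samples by default; a range normalization is available behind a
flag.  The expression input is size-factor-normalized, log1p-transformed
counts; because the score is rank-based the log is immaterial (tested), but
it keeps the input on a familiar scale.  Sets with no member present score
NaN ("missing"), sets covering *every* gene are rejected.

**Stage trends.** Per-signature Kruskal–Wallis across ≥ 2 groups, with the
conventional star buckets at 0.05/0.01/0.001/0.0001.  In the two-group case
this is equivalent to a rank-sum test (tested against it).

## Feature screening

The screen runs strictly in order: (1) *clean* — drop features with any
inoperable/non-finite value or zero variance, logging a reason per drop
(the cleaning criterion is "non-finite or inoperable", the only reading of
feature hygiene that does not discard all data); (2) *redundancy* — greedy
correlation pruning at |r| > 0.95, walking features in ascending screening-p
order so the stronger of a correlated pair survives; (3) *screen* —
two-sample pooled-variance Student's t (Welch behind a flag) plus the
Gaussian closed-form Bhattacharyya coefficient (histogram form behind a
flag; the closed form agrees with numerical integration of √(pq) to 1e-6,
enforced by test).  No multiple-testing correction is applied to the
radiomic screen, and significance thresholds use strict inequality — a
feature at exactly p = 0.05 sits on the Manhattan-plot line and is not
flagged.

The screened set is then reduced in two phases: one representative per
(family, feature name) chosen uniformly at random among its significant
parameter variants — the only seeded stage of the screen — and finally the
k smallest-p features, k matched to the number of significant genomic
predictors, with boundary ties broken lexicographically by feature id.

## Staging model

`RadiogenomicStagingModel(genomic, radiomic, labels).fit(config)` runs
backward feature elimination over the *pooled* candidate set (both
categories weighted equally): at each step the feature whose removal leaves
the best-scoring remainder is dropped, every cap-respecting subset along
the path is scored, and the best one — by CV sensitivity, then CV accuracy,
then fewer features, with deterministic lexicographic tie-breaks — is
refitted on all training cases.  Sensitivity leads because the clinical
cost of calling an extra-vesical tumor intra-vesical (a missed invasive
cancer) exceeds that of the reverse error.  At most 8 features per category
can be retained, enforced structurally.

Subsets are scored by stratified k-fold cross-validation (default 5 folds,
capped at the minority class size, seeded fold assignment fixed for the
whole elimination) with pooled out-of-fold confusion counts.  Features are
z-scored with statistics from the training folds only.  The five classifier
families use standard formulations — Gaussian naive Bayes, soft-margin
linear SVM (C = 1), k-NN (k = 3, Euclidean), L2 logistic regression, CART
tree with depth cap 3 — all hyperparameters exposed in `StagingConfig`.
For naive Bayes the CV inner loop uses a vectorized implementation whose
decisions match `sklearn.naive_bayes.GaussianNB` exactly (tested); the
Gaussian likelihood ratio is invariant to per-feature affine scaling, so
the z-score step is skipped there.

External validation freezes the trained predictor set: `predict` matches
features by name, raises on any missing selected feature (no silent
imputation), and is invariant to column order.

## Synthetic cohorts

The generator emulates the *structure* of a two-center radiogenomic study —
a 28-case training cohort (18 intra- / 10 extra-vesical) and a 12-case
external test cohort with MR volume + mask pairs, gene-level counts, stage
labels and a 75-set signature collection — under known ground truth.  No
distributional description of the real images or counts is available, so
all generator choices are documented stand-ins:

- **Tumors** are random ellipsoids (radii 22–32% of the volume extent,
  class-independent) with smoothed-noise boundary perturbation, kept as the
  largest connected component, ≥ 100 voxels.  Size distributions match
  across classes *by construction* so volume carries no stage signal —
  mirroring the fact that intra- and extra-vesical tumors can have
  identical sizes, which is what makes texture interesting.
- **Texture** inside the mask is a Gaussian random field (smoothed white
  noise).  Extra-vesical tumors get a longer correlation length
  (σ = 0.8·(1 + effect)) and a larger marginal SD (0.12·(1 + effect/2));
  at `texture_effect = 0` the two class-conditional generators are
  byte-identical.  The smoothing-radius → GLCM mapping is monotone and
  cheap, which is why a Gaussian field was chosen.
- **Counts** follow K_gj ~ NB(mean = s_j·q_g·2^(β_g·x_j), dispersion α),
  x_j = 1 for extra-vesical samples; α = 0 degenerates to Poisson.
  Library-size factors s_j are log-uniform in [0.5, 2] so normalization is
  actually exercised.  Baseline expressions q_g (log-uniform, 20–2000) and
  the identity of the planted DEGs are drawn from cohort-seed-*independent*
  streams: they are properties of the genes and the disease, shared across
  cohorts, which is what makes external validation meaningful — a
  train-fitted classifier must see the same biology in the test cohort, as
  it would in reality.  Per-cohort seeds control only sampling noise, size
  factors and case-level draws.
- **Planted DEGs** (default 50 at |log2fc| = 2, dispersion 0.1) always
  include the nine canonical stage-associated genes with their known
  directions — HOXB5, DHRS3, FABP4 higher in intra-vesical disease;
  TAGLN2, HIST1H1D, HIST1H2BD, H2AFX, CLDN3, PLAUR higher in
  extra-vesical — so `n_de_genes` must be 0 or ≥ 9; the remainder split
  alternately between directions.
- **Gene sets** (default 75 of size 30): one set enriched in each planted
  direction (planted genes padded with nulls), the rest random.
- **Seeding**: one global seed streams to per-case and per-stage sub-seeds
  via `SeedSequence([seed, stream])`, so regeneration is bit-identical and
  inserting a case never reshuffles the others.
- **Heterogeneity** (default 0): with `heterogeneity = h > 0`,
  extra-vesical cases alternate between a texture-dominant phenotype
  (expression effect scaled by 1 − h) and an expression-dominant one
  (texture scaled by 1 − h).  This models tumor subpopulations visible to
  one modality but muted in the other — the regime in which integrating
  modalities genuinely pays, and the construction used by the
  model-comparison study (texture_effect 0.6, log2fc 1.0, h 0.8, chosen
  once by Monte-Carlo calibration so that each single-omics baseline lands
  well below ceiling while the integrated model reliably exceeds both, and
  verified on disjoint seed streams).

What the cohorts do **not** emulate: MR physics (bias fields, coil
profiles, partial-volume effects), DICOM metadata, realistic gene–gene
correlation structure, batch effects, or clinical covariates.  Passing
tests therefore demonstrate that the *pipeline machinery* is correct and
calibrated — matrix builders exact against brute force, null screens at
their nominal rates, planted effects recovered with controlled FDR, caps
enforced, runs reproducible — not that any particular accuracy would be
attained on real patients.

## Orchestration

`run_all` executes simulate → radiomics → genomics → select → train →
evaluate, writing every stage's outputs before the next begins and ending
with a manifest (config, seed, per-file SHA-256 checksums).  Rerunning the
same configuration reproduces every output checksum; NIfTI files are
written uncompressed because gzip headers embed timestamps.  The
orchestrated default uses a moderate radiomic grid (bins 2–4, kernels 1–2,
all four angles, 869 records per case); the full 8×5×4 sweep remains
available for dedicated extraction runs.  The stage-label reader accepts
raw TNM stages and maps Ta/Tis/T1/T2 → intra-vesical and T3/T4/N+/M+ →
extra-vesical (the grouping is stated inconsistently in the source
literature; this package adopts the cohort-definition convention and keeps
the mapping in one table, `io.TNM_TO_STAGE`).

## Study problem sizes

The reporting script (`scripts/acceptance.py`) and the acceptance tests fix
the following sizes as the package's study conditions: single-triple census
on one synthetic case; 50 seeded RFE trainings at 3-fold CV with 10
features offered per category; null screens over 2000 independent features
(14 + 14 cases) and 2000 null genes (10 + 10 samples); DEG recovery at
50/2000 planted genes, |log2fc| = 2, 10 + 10; the model comparison over 20
seeded bimodal cohort pairs (28 train / 12 test) with the NB family; and a
double end-to-end run for checksum identity.

## Known limitations

- Dispersion estimation without shrinkage is noisy at n ≈ 10 per group; the
  pooled-df t reference compensates at the null but power at small fold
  changes is below what a shrinkage estimator would give.
- The radiomic screen is univariate; multivariate structure is only
  captured later, by RFE.
- Backward elimination is a greedy wrapper: it explores one path through
  the subset lattice, and with near-tied CV scores the selected set can
  change with the fold seed (it is deterministic for a fixed seed).
- Shape features assume the in-plane axes of each axial slice are the
  grid's row/col axes; oblique acquisitions are out of scope.
- Several feature names attributed to the original in-house extraction
  tool have no published formula and are not reproduced; the catalog here
  is the consensus-formula subset at the stated per-family counts.
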