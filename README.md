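# radstage

Radiogenomic staging of bladder cancer: joint analysis of MR tumor radiomics
and RNA-seq genomics for binary **intra- vs extra-vesical** stage
classification.

Accurately deciding whether a bladder tumor is still confined within the
bladder wall (intra-vesical) or has grown beyond it (extra-vesical) drives
the choice between organ-preserving treatment and radical cystectomy, and
axial imaging alone mis-stages a substantial fraction of patients in both
directions.  `radstage` implements a complete, tested pipeline that

1. extracts **3D radiomic features** (first-order, GLCM, GLRLM, GLSZM, GLDM,
   NGTDM and shape families) from MR volumes with aligned binary tumor
   masks, sweeping the discretization bin count (N = 2^x, x = 1..8), the
   kernel/offset size (1..5) and the four in-plane angles (0/45/90/135
   degrees);
2. derives **genomic predictors** from gene-level RNA-seq counts: a
   simplified negative-binomial Wald test for differential expression
   (median-of-ratios size factors, method-of-moments dispersion,
   Benjamini–Hochberg FDR), direction-consistent DEG intersection across
   datasets, and per-sample ssGSEA signature scores with Kruskal–Wallis
   stage-trend tests;
3. **screens and integrates** both feature families — cleaning, correlation
   pruning, Student's t / Bhattacharyya-coefficient screening, random
   de-duplication of parameter variants, and p-value-ordered capping of the
   radiomic set to the size of the genomic set;
4. trains and validates **staging classifiers** (Gaussian naive Bayes,
   linear SVM, k-NN, logistic regression, decision tree) with recursive
   feature elimination scored by cross-validated sensitivity, never
   retaining more than 8 features per category.

Because patient MR and RNA-seq data of this kind cannot be redistributed,
the package ships a first-class **synthetic cohort generator** with known
ground truth: tumor volumes whose *texture* (not size) separates the
classes, NB-distributed counts with planted direction-consistent DEGs, and
signature collections enriched in each direction.  Every downstream stage is
exercised and calibrated against that ground truth.

## The statistics at the core

**Differential expression.** For gene *g* with normalized counts
y = K/s (size factors s by median-of-ratios), the two-group Wald statistic
is

    W_g = log2fc_g / SE_g,   SE_g^2 = (1/n1)(E[1/s]/mu_1 + alpha_g) + (1/n0)(E[1/s]/mu_0 + alpha_g)

with method-of-moments dispersion alpha_g = max(0, (Var - mu E[1/s]) / mu^2)
pooled across groups, referred to a t distribution with n1 + n0 − 2 df, and
BH-adjusted across genes.

**ssGSEA.** Per sample, genes are ranked by expression (average ranks on
ties); for a set S the score is the sum over all gene positions of the
difference between the weighted in-set rank CDF (weights rank^alpha,
alpha = 0.25) and the uniform out-of-set CDF.

**Bhattacharyya coefficient.** For per-class Gaussian feature summaries,
BC = exp(−D_B) with

    D_B = (mu1 − mu2)^2 / (4 (s1^2 + s2^2)) + 0.5 ln( ((s1^2 + s2^2)/2) / (s1 s2) )

so BC = 1 for identical classes and → 0 as they separate.

**Evaluation.**  Positive class = extra-vesical; sensitivity = TP/P,
specificity = TN/N, accuracy = (TP+TN)/(P+N), with model selection
prioritizing sensitivity (a missed extra-vesical tumor is clinically worse
than a false alarm).

## Worked example

```python
from radstage import CohortConfig, generate_cohort
from radstage.genomics import nb_wald_de

cohort = generate_cohort(CohortConfig(n_intra=18, n_extra=10, seed=7))
de = nb_wald_de(cohort.counts, cohort.labels)
print(int(de["significant"].sum()))          # 54 significant genes at FDR 0.05
print(de[de["significant"]].sort_values("adj_p").head(3)[
    ["log2fc", "adj_p", "direction"]].round(3))
```

```
           log2fc  adj_p   direction
GENE00943   2.218    0.0  up_in_high
GENE00639  -2.412    0.0   up_in_low
GENE00308   1.812    0.0  up_in_high
```

The cohort plants 50 genes at |log2 fold change| 2; the test recovers 54
calls of which 50 are planted (the `direction` column says which class the
gene is higher in).  Building the integrated staging model on a cohort
where texture and expression carry complementary signal:

```python
model = train_rfe(genomic_scores, radiomic_features, cohort.labels, "NB",
                  StagingConfig(family="NB", seed=7))
print(model.summary())
```

```
Radiogenomic staging model
==========================
classifier family : NB
per-category cap  : 8
CV folds / seed   : 5 / 7
CV sensitivity    : 1.000
CV accuracy       : 1.000
genomic selected  (1):
  - SIG_UP_IN_HIGH
radiomic selected (2):
  - gldm|DependenceEntropy|b3|k1
  - glcm|ClusterProminence|b3|k2|a90
```

Validated on an independent 12-case synthetic cohort this model reaches
sensitivity 1.00, specificity 0.83, accuracy 0.92 — and across 20 seeded
cohort pairs the integrated model's mean accuracy exceeds both the
genomic-only and the radiomic-only baselines.

The whole pipeline (simulate → radiomics → genomics → select → train →
evaluate, with a checksummed run manifest) is also available from the shell:

```bash
radstage run-all --seed 0 --out runs/demo
radstage radiomics --images runs/demo/simulated/train/images \
                   --masks runs/demo/simulated/train/images \
                   --grid default --out features.csv
```

## Layout

- `src/radstage/synthetic.py` — ground-truth cohort generator
- `src/radstage/radiomics/` — discretization, texture matrices, shape, sweep
- `src/radstage/genomics.py` — size factors, NB Wald DE, ssGSEA, stage tests
- `src/radstage/selection.py` — cleaning, screening, capping
- `src/radstage/staging.py` — `RadiogenomicStagingModel` / `StagingResults`
- `src/radstage/pipeline.py`, `cli.py`, `io.py` — orchestration and formats
- `docs/methods.md` — modelling assumptions, parameter choices, limitations
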