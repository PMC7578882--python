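# Methods

`gutmarkers` implements a complete gut-microbiome marker-discovery study on
OTU count tables: diversity profiling, differential-abundance screening,
random-forest marker selection with a cross-validation error curve, a
tree-vote probability-of-disease (POD) index evaluated by ROC/AUC, and
correlation of marker abundances with clinical indicators. This note records
the models, conventions and design choices, and what the synthetic-data
tests do and do not demonstrate.

## The analysis pipeline

Inputs are a samples x OTUs table of nonnegative integer read counts plus
per-sample metadata (group label CASE/CONTROL, cohort tag, clinical
indicators). All statistics operate on relative abundances (total-sum
scaling, no pseudocount); rarefaction (random subsampling without
replacement to a common depth, multivariate hypergeometric) is applied
before diversity estimation by default, since richness estimators are
library-size sensitive. Whether to rarefy before diversity is exposed as
config (`diversity_on_rarefied`), and the rarefaction depth defaults to the
minimum library size.

### Diversity

* **Shannon** H = −Σ pᵢ ln pᵢ over positive proportions; natural log by
  default (a `base` switch gives log2). The uniform vector of k taxa gives
  ln k.
* **Chao1**, bias-corrected: S_obs + F1(F1−1)/(2(F2+1)) with F1/F2 the
  singleton/doubleton counts. The bias-corrected form is defined at F2 = 0.
* **ACE** with the standard rare/abundant threshold of 10 reads: abundant
  taxa counted directly, rare taxa scaled by the coverage estimate
  C = 1 − F1/N_rare with the squared-CV correction. When every rare read is
  a singleton C = 0 and the estimator is undefined; the bias-corrected Chao1
  is returned instead.
* **Bray–Curtis** on relative abundances; **PCoA** by eigendecomposition of
  the double-centred Gower matrix (via scikit-bio), axes with non-positive
  eigenvalues dropped; **PCA** as covariance eigendecomposition. NMDS is
  deliberately not provided: for testing group separation it adds nothing
  over PCoA, at the cost of an iterative stress minimiser.
* **Group overlap** (Venn accounting): an OTU is "present" in a group when
  its summed count there is ≥ 1 (configurable `presence_min`).

### Differential abundance

* **Wilcoxon rank-sum screen**, two-sided, per feature. Exact enumeration
  when both groups have ≤ 8 observations and no ties; otherwise the
  tie-corrected normal approximation on midranks *without* continuity
  correction — this makes the two-group Kruskal–Wallis test algebraically
  identical (z² = H), which the tests assert to 1e-9.
* **No multiple-testing correction by default.** The screening rule is a raw
  p < 0.05 per feature; this is a deliberate, prominent reproduction choice
  for this analysis style, and a Benjamini–Hochberg mode (`bh=True`) is
  available for users who want FDR control.
* **LDA effect size** (LEfSe-style, restricted to the single-factor
  two-class design): Kruskal–Wallis prescreen at α = 0.05, then for passing
  features a bootstrap-averaged (30 class-stratified resamples, 2/3 size)
  discriminant effect on abundances scaled by 1e6. With one feature the
  unit-norm LDA direction is ±1, so the projected group-mean difference
  equals the scaled raw mean difference; signed bootstrap differences are
  averaged before the absolute value so null noise cancels. The reported
  score is log10 of the effect, floored at 1 (near-zero effects cannot pass);
  the default pass threshold is 2.0. Zero-variance features score 0.

### Marker selection

1. Features passing the Wilcoxon screen are ranked once by random-forest
   permutation importance (mean decrease in accuracy, 10 permutations per
   feature) on the full discovery cohort. Zero-variance features rank last.
2. For nested prefixes of the ranking (sizes 1..K), five trials of
   stratified fivefold cross-validation measure the held-out
   misclassification rate ("error" = pooled held-out error; stratification
   protects imbalanced cohorts).
3. The **min-error-plus-SD rule**: cutoff = min mean error + across-trial SD
   at the argmin (ties at the minimum resolve to the smallest size);
   candidate sizes are those with mean error strictly below the cutoff
   (relaxed to ≤ when the SD is 0, else the minimum itself would be
   excluded); the chosen set is the smallest candidate prefix.

Because the ranking is computed once on all discovery data, the curve's
error estimates are optimistic (selection leakage). That two-stage shape is
the procedure this pipeline reproduces; an honest mode that re-ranks
features inside every training fold is available (`rank_within_folds=True`,
off by default). The SD "at the corresponding point" is the SD across the
five trial means, the convention of rfcv-style error curves.

Forests default to 500 trees (the R randomForest default, matching the
"all parameters default" convention of this analysis style). The
simulation-heavy tests and the acceptance script use 100 trees: with ≤ 15
screened features and a few hundred samples, error curves stabilise well
below that, and it keeps a ~1200-fit curve tractable on one CPU. Problem
sizes used by the tests are stated in each test.

### POD index and ROC

The final ensemble is trained on the selected marker abundances only. For a
sample, POD = (number of trees voting CASE) / (total trees) ∈ [0, 1]. The
literal case/control vote *ratio* is available (`ratio=True`) but is
unbounded and undefined when no tree votes control; both induce the same
ordering, hence identical ROC/AUC — the fraction is the default. AUC is the
normalised Mann–Whitney statistic (ties count ½); the 95% CI uses DeLong's
structural-components method (the pROC default convention), with placements
computed by midranks so tied scores are handled exactly. Held-out
evaluation refuses cohorts sharing sample ids with the training set.

### Clinical correlation

Spearman rank correlation (midranks) of marker abundances against clinical
indicators, pairwise-complete: each cell uses only samples with both values
observed and records n_used; cells with < 3 complete pairs are flagged
not-computable rather than raising. P-values use the t approximation with
n−2 df, switching to exact permutation enumeration for n ≤ 9. The published
figure this mirrors reports "partial" Spearman correlations without naming
the adjustment set, so plain Spearman is the default; an optional partial
mode rank-regresses both variables on a stated covariate list and
correlates the residuals.

## The synthetic-data generator

Real 16S data are unavailable at desk scale, so cohorts are simulated with
known ground truth:

* **Base community**: log-normal relative abundances (mean 0, SD 1.5 before
  calibration), normalised to a composition over `n_otus` (default 105).
* **Planted markers**: `n_diff` OTUs (default 5) drawn from the 50th–90th
  abundance percentile band (consistently detectable, never dominant); the
  case profile multiplies them by 2^lfc (default lfc = 3) or divides,
  then renormalises. Directions are assigned greedily so the planted mass
  change nearly cancels — otherwise compositional closure would hand every
  unplanted OTU a spurious fold change of the renormalisation factor, which
  is a real artifact of compositions but would confound tests that assume
  only planted OTUs differ.
* **Counts**: per sample, a library size from a log-normal (median 10,000
  reads, log-SD 0.3), a composition from a Dirichlet centred on the group
  profile with concentration c = 20, counts multinomial — i.e.
  Dirichlet–multinomial. c = 20 (overdispersion θ = 1/c = 0.05) is in the
  range Dirichlet-multinomial fits to stool communities typically report;
  it makes single OTUs individually imperfect classifiers, which is what
  gives the CV error curve a genuine multi-marker optimum.
* **Sparsity calibration**: the marginal zero fraction is driven to the
  target (default 0.5) by scaling the log-abundance spread (a temperature on
  the base profile), using the analytic beta-binomial zero probability
  averaged over OTUs and library sizes. Infeasible targets raise with a
  diagnosis. Calibration library sizes come from the biology stream so the
  profile is identical across draws of the same spec.
* **Clinical indicators**: normal per group with shifts (in pooled-SD units)
  anchored to the renal-failure phenotype: creatinine +1.5, urea +1.7,
  eGFR −2.5, albumin −1.7, haemoglobin −1.0, phosphate +0.6 SD, in recorded
  units (µmol/L, mmol/L, mL/min/1.73 m², g/L). Indicators depend on counts
  only through the group label; richer correlation structure is out of scope.
* **Streams**: one master seed; biology (profile, planted set) depends on
  the seed alone, sample-level randomness also on a `draw` index. Two draws
  of the same spec are therefore independent cohorts from the same
  populations — that is how validation and independent cohorts are emulated.
  A `site_effect_sd` option multiplies both group profiles by a shared
  log-normal shift *after* planting, emulating a second sampling region with
  the same disease biology.

**What passing tests show — and don't.** The generator reproduces sparsity,
overdispersion, compositionality, library-size variation and planted
effects, so the tests demonstrate that the pipeline recovers known signal
and controls type-I error under those conditions. It does not emulate
phylogenetic correlation between taxa, taxon-specific biology, batch or
sequencing-run effects, or abundance-dependent detection bias; performance
numbers on synthetic cohorts say nothing about absolute AUCs achievable on
real cohorts.

The fixed worked-example fixture (`spike_worked_example`) is 10+10 samples x
30 OTUs with 5 planted markers at lfc = 2.5 and c = 10: at that effect and
noise level no single OTU suffices, so the error curve genuinely selects a
multi-marker set, and end-to-end discovery recovers ≥ 4 of the 5 planted
OTUs — pinned as a regression test.

## Numerical and degenerate-input conventions

* Rank tests return p = 1 when all pooled observations are identical.
* `select_optimal_markers` breaks argmin ties toward the smallest size; an
  all-equal curve with zero SD chooses size 1.
* Rarefaction drops samples below depth with a warning; depth ≤ 0 is an
  error; a sample exactly at depth is returned unchanged.
* PCoA drops axes with eigenvalues ≤ 1e-12 x the largest; proportions
  explained are relative to the positive spectrum.
* DeLong variance uses ddof = 1 placements; CIs are clipped to [0, 1].
* BIOM-JSON I/O implements the v1.0 dense/sparse JSON schema directly (reads
  both, writes dense).
* Model persistence uses joblib with a format-version tag; votes round-trip
  bit-identically.

## Known limitations

* The two-stage selection (global ranking, then CV) leaks ranking
  information into the error curve; honest nested CV is available but not
  the default, by design.
* The raw p < 0.05 screen does not control FDR across thousands of OTUs.
* The POD index is a vote share, not a calibrated probability.
* LEfSe-style scoring here covers the two-class, no-subclass design only.
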