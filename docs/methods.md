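# Methods

This note documents the statistical model behind `lexrsa`, the
parameter choices that matter, what the synthetic-data generator does
and does not emulate, and the numerical conventions used throughout.

## The analysis model

The pipeline asks whether the multi-voxel response geometry of a region
of interest carries orthographic or semantic information about written
words, and whether that differs between subject groups.  Conditions are
single words; all second-order statistics operate on representational
dissimilarity matrices (RDMs) over the word set, vectorized as the
strictly-lower triangle in row-major order (a fixed convention so every
correlation is bit-for-bit reproducible).

### Theoretical RDMs

**Orthographic model.**  A position-weighted Levenshtein distance: the
usual insert/delete/substitute dynamic program, except that any edit
consuming the first or last character of either string costs `w_edge`
(default 2.0) instead of 1, and letter matches cost 0.  With
`w_edge = 1` this is exactly the plain Levenshtein distance, and the
weighted distance is never smaller than the plain one.  The form is a
deliberate design choice: the idea of weighting shared initial and
final letter positions more heavily admits many functional forms, and
we use the minimal monotone generalization of the classical distance
that has that property.  `w_edge` is exposed in configuration.

**Semantic model.**  Pairwise distances between word-embedding vectors,
which are *consumed as input* — the package never trains embeddings.
Default metric is Euclidean (low-dimensional neighbor-embedding spaces
are conventionally read with Euclidean distance); cosine is available.

**Confounds.**  Absolute pairwise differences of log₁₀ lexical
frequency (per-million counts are heavily right-skewed) and of letter
length.  When a single combined confound matrix is wanted, each
confound RDM is min-max scaled over its off-diagonal entries before
entrywise averaging — a plain average of raw matrices would be
dominated by whichever variable has the larger numeric range.

**Design check.**  Stimulus sets are only interpretable if the two
model RDMs are decorrelated; `design_check` reports the Spearman
correlation plus a condition-label permutation p-value and passes when
the null of no association is *not* rejected.

### Pattern estimation (GLM)

Per run, one regressor per word (pooling its repetitions): a boxcar at
the event onsets convolved with a canonical double-gamma HRF
(peak 6 s, undershoot 16 s, unit dispersions, 6:1 ratio, 32 s kernel —
the conventional constants, configurable), plus an intercept and a
discrete-cosine drift basis implementing a 128 s high-pass cutoff
(K = ⌊2·N·TR/cutoff⌋ basis functions).  Ordinary least squares with
run-specific residual variance; condition estimates are converted to
t-values against the implicitly modelled baseline (unmodelled scans,
including the symbol-string trials).  No autocorrelation model is
applied: the t-maps feed a relative geometry analysis rather than
univariate inference, and serial correlation inflates all conditions'
variances similarly within a run.  This is a stated limitation, not an
oversight.

### Cross-validated neural RDMs

For conditions a, b and a partition with train runs T and test runs S,

    d(a, b) = (x̄ₐᵀ − x̄ᵦᵀ) · (x̄ₐˢ − x̄ᵦˢ) / V,

averaged over the partition scheme and normalized by voxel count V so
values are comparable across regions of different size.  Because train
and test noise are independent, E[d(a, a)] = 0 and entries can be
negative; the diagonal is exactly zero by construction and never enters
any correlation.  Dead voxels (zero variance across all samples) are
removed first.

Two partition schemes: `ordered_pairs` (all ordered pairs of distinct
runs, 12 partitions for 4 runs) is the default because train = test
pairs are not cross-validated and reintroduce the positive bias the
estimator exists to remove; `all_pairs` (r² = 16 partitions for 4 runs)
is provided for comparability with analyses that report that count.
No noise-covariance whitening is applied (a multivariate noise
normalization flag is reserved but off by default).

### Second-order inference

Per subject and model: rank-transform the neural, model and confound
RDM vectors (average ranks for ties), residualize neural and model
ranks on the confound ranks by least squares with intercept, and report
the Pearson correlation of residuals — the partial Spearman rho.  With
no confounds this equals the textbook Spearman coefficient exactly.

Group inference: two-sided Wilcoxon signed-rank against a zero median
within each group (exact null for n ≤ 25 with untied ranks, normal
approximation with continuity correction otherwise; exact zeros are
dropped, following Wilcoxon's original rule — noted in output
metadata); pooled-variance two-sample t between groups by default
(rank-sum available).  Benjamini–Hochberg q-values are computed across
the model dimension within each group × ROI family by default; a
config switch pools the correction across the whole ROI × model grid,
since a two-test family is unusually small and some users will prefer
the broader family.

Factorial follow-ups use least-squares linear models with Type II sums
of squares — with unbalanced groups (e.g. 20 vs 22 subjects) Type I
would depend on term order.  Tukey(-Kramer) studentized-range post hocs
use the pooled within-cell variance; with two cells the adjusted p
reduces to the unadjusted pooled t-test p.  The gradient factor for the
ventral-stream analysis groups posterior {FG1, FG2} against anterior
{FG3, FG4} subregions.  The mixed Group × Repetition ANOVA on naming
latencies uses the classical univariate decomposition (between error:
subjects within groups; within error: repetition × subjects within
groups) with no sphericity correction by default.

### Behavioural summaries

Cohen's d and t are computed from printed group summaries with the
pooled-SD convention, signed as (first group − second group); RT
trimming removes values outside mean ± 2.5 SD per subject in a single
pass (no re-iteration, which would change the retained set); the
efficiency score is (accuracy / response time) × 10.

## The synthetic-data generator

The generator emulates the statistical structure of a 33-word,
two-category, four-run event-related reading experiment (TR 1.23 s,
three repetitions per word per run plus symbol-string baseline trials;
34 words reproduce the 136-trials-per-run variant).  Its purpose is
parameter recovery: the geometry that the analysis is supposed to
detect is planted explicitly.

* **Word sets**: random letter strings with lengths drawn from
  N(6.85, 1.7) clipped to [2, 10]; log-normal per-million frequencies
  clipped to [1, 126]; categories alternating over the index; every
  fourth token replaced by a single-letter substitution of its
  predecessor to plant orthographic neighbours across category
  boundaries.  Embeddings are category-centered Gaussian clusters, so
  the semantic RDM carries category structure.
* **Decorrelation constraint**: draws are rejected until the Spearman
  correlation between the orthographic and semantic model RDMs is at
  most 0.02 in magnitude, mirroring the stimulus-selection constraint
  of decorrelated models.  This constraint is load-bearing: residual
  model correlation is shared by every simulated subject of a cohort
  and is the main threat to the calibration of null-model tests.
* **Geometry planting**: the target RDM is
  w_sem · scale(sem) + w_orth · scale(orth) (each component min-max
  scaled); latent coordinates are its classical-MDS embedding.  Mixture
  RDMs are generally not Euclidean-embeddable, so the embedding
  truncates clipped negative eigenvalues; with the default
  latent_dim = 16 the latent pairwise distances track the target at
  Spearman ≈ 0.98–0.99 for 33 words (8 dimensions would give ≈ 0.91,
  which is why the default is higher).
* **Patterns**: one fixed random linear map (latent → voxels) per
  subject, shared across runs, plus independent run-level Gaussian
  noise.  Sharing the map across runs is what makes the cross-validated
  distances unbiased estimates of the latent geometry.  Optionally the
  amplitude patterns can be rendered into BOLD series through the same
  HRF design machinery the GLM uses, which makes the noiseless
  simulate→estimate round trip exact.
* **Timing**: fixation 350 ms + blank 700 ms + stimulus 700 ms +
  uniform jitter in [550, 1550] ms (the jitter distribution is a
  choice; only its range is given by the emulated design).

### Default parameters

| parameter | default | rationale |
| --- | --- | --- |
| n_words / n_categories | 33 / 2 | emulated stimulus design (34 supported) |
| n_runs × n_repetitions | 4 × 3 | emulated session structure |
| n_voxels | 150 | typical ROI size after dead-voxel removal |
| latent_dim | 16 | smallest dimension with ≥ 0.95 planting fidelity |
| noise_sd | 0.7 | see below |
| w_edge | 2.0 | edge edits twice as expensive; reduces to plain at 1 |
| max_model_corr | 0.02 | decorrelation constraint on drawn word sets |
| TR | 1.23 s | emulated acquisition |

`noise_sd` controls the single most important trade-off.  It was fixed
by a design-stage grid over {0.5, 0.6, 0.7, 0.85} against the two
calibration requirements the generator's defaults must satisfy
simultaneously: (i) with w_orth = 0, the signed-rank test on the
orthographic model must reject at ≈ the nominal 5% rate (measured
0.125 / 0.067 / 0.050 / 0.033 across the grid), and (ii) groups with
semantic weights 0.8 vs 0.4 at n = 20 per group must be separable in
the large majority of replicate experiments (measured 1.0 / 1.0 /
0.93 / 0.63).  noise_sd = 0.7 is the value satisfying both with margin;
it yields single-subject model correlations of roughly 0.1–0.45,
within the range seen in ROI-level RSA.  The value was frozen before
the acceptance suite was written and is not adjusted per experiment.

### What passing tests do and do not show

The generator's noise is white across voxels, runs and subjects.  Real
fMRI patterns have spatial and temporal autocorrelation, scanner drift,
motion artefacts, between-subject anatomical variability and
non-Gaussian outliers, none of which are modelled.  Recovery and
calibration results on this generator therefore validate the
*statistical machinery* — estimator unbiasedness, test calibration,
confound partialling, monotone sensitivity to planted effect size —
not the robustness of the pipeline to realistic fMRI artefacts.
Conclusions about real data additionally rest on the upstream
preprocessing and denoising that this package deliberately leaves out
of scope.

## Numerical conventions and degenerate inputs

* RDM constructors validate symmetry, zero diagonal and finiteness;
  construction fails loudly rather than silently symmetrizing.
* Spearman ties take average ranks everywhere.
* Zero-variance RDM vectors, zero pooled SDs, constant factorial
  responses, all-dead voxel sets and sub-minimum sample sizes raise
  errors naming the offending quantity instead of returning NaN.
* Zero residual variance in the GLM yields an explicit infinite-t
  warning (t = 0 where the estimate is also zero).
* Classical MDS clips negative eigenvalues to zero and warns; the
  generator suppresses the warning internally where truncation is
  expected by design.
* All randomness flows from a single integer seed through a
  SeedSequence hierarchy (per-stage, then per-subject), so identical
  configurations produce byte-identical result tables.

## Known limitations

* No AR(1)/prewhitening or nuisance-regressor denoising in the GLM.
* No multivariate noise normalization in the distance estimator (flag
  reserved).
* The exact functional form of the edge-weighted edit distance is a
  design choice among several that "weight initial and final overlap";
  results depending on fine orthographic gradations should be checked
  for robustness across `w_edge`.
* Between-group inference offers t and rank-sum variants; for small
  groups with heavy-tailed correlation distributions the two can
  disagree, and the choice is surfaced in configuration rather than
  hidden.
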