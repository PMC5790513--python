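# Methods

`sigforge` implements, as a reusable and fully tested pipeline, the
derivation and prognostic validation of a tumor-type-specific hypoxia
gene-expression signature. The pipeline has five scientific stages, each
exposed as its own module, plus a synthetic-data generator that plants
ground truth so every stage can be scored without external data.

## 1. The analysis

### 1.1 In-vitro seed-gene discovery (`de_counts`, `seeds`)

Each cell line contributes a paired hypoxia/normoxia count experiment.
Differential expression follows the count-based (DESeq-style) contract:

* **Size factors** by median-of-ratios: for genes positive in every sample,
  `s_j = median_i (K_ij / geomean_i)`, rescaled so the geometric mean of the
  factors is 1. The median is taken on the linear ratio scale.
* **Dispersion** under the NB2 convention `var = mu + alpha * mu^2`. The
  gene-wise estimate is within-condition method-of-moments,
  `alpha_i = max((pooled var - pooled mean) / mean^2, 1e-8)` with the pooled
  variance computed about the condition means. With three replicates per
  condition this estimate has ~4 degrees of freedom and is far too noisy to
  test against directly: in null simulations the Wald test below makes tens
  of Benjamini–Hochberg discoveries per 5,000 null genes when fed the raw
  gene-wise values. The fitting path therefore applies the classical
  conservative sharing rule: a mean–dispersion trend
  `alpha(mu) = a0 + a1/mu` is fitted to the gene-wise estimates by lightly
  trimmed (3 SD, three passes) least squares, and each gene's test
  dispersion is the **maximum** of its own estimate and the fitted trend.
  This restores null calibration (0–1 BH calls per 5,000 null genes in our
  simulations) at a negligible power cost for the strong effects the screen
  targets. The bare method-of-moments estimator remains available as
  `estimate_dispersion`.
* **Testing**: per gene, an NB GLM with log link and a condition indicator
  is fitted by IRLS at fixed dispersion (size factors as offsets); the Wald
  statistic `coef / SE` is referred to the standard normal; BH adjustment is
  applied over all genes expressed in at least one sample (all-zero genes
  are excluded from testing and from the BH denominator); genes whose IRLS
  does not converge in 50 iterations are reported non-significant with
  p = 1 and counted. A gene is *induced* when `fdr < 0.05` and the fitted
  fold change is at least 2 (`log2fc >= 1`).

Genes induced in **all** cell lines are the seed candidates; optional
filters intersect them with a protein-coding list and with the gene
universe shared by all patient cohorts. To quantify how many genes would
recur by chance, `mc_overlap_null` draws one uniform random gene set per
observed per-line set size (without replacement within a set, independent
across sets) and counts genes in at least *k* sets; `exact_overlap_null`
computes the expectation in closed form — a fixed gene's membership count
is Poisson-binomial with `p_i = size_i / universe`, evaluated by exact
dynamic-programming convolution — and serves as the Monte Carlo routine's
oracle in the test suite.

### 1.2 In-vivo phenotype discovery (`cluster`, `de_linear`)

Training-cohort tumors are clustered into two groups by K-means (Lloyd's
algorithm, Euclidean distance, best of 1000 random restarts) on the log2,
per-gene median-centered expression of the seed genes; tumors are the
clustered points and genes the feature dimensions. No scaling beyond
median-centering is applied. The cluster with the larger mean centered
seed-gene expression is labeled **high-hypoxia**. Degenerate inputs (fewer
than two distinct tumor profiles, or an empty cluster) raise an error; an
exact tie in cluster means falls deterministically to the first sample's
cluster with a warning. K-means is backed by scikit-learn's Lloyd
implementation, which relocates rather than redraws empty clusters; with
k = 2 and the degenerate-input guard this is equivalent in practice.

The high-vs-low contrast on all genes uses the empirical-Bayes moderated t
statistic: gene-wise pooled variances `s_g^2` (df `n - 2`) are shrunk to
`s~_g^2 = (d0 s0^2 + d_g s_g^2) / (d0 + d_g)`, with `(d0, s0^2)` estimated
by moment-matching the scaled-F marginal of the `s_g^2` on the log scale
(digamma/trigamma inversion, Newton iteration for the trigamma inverse).
When the between-gene spread of log variances does not exceed its expected
sampling spread, the prior df is infinite and the prior variance is set to
the geometric mean of the gene variances, so homogeneous inputs are
returned unshrunk and the moderated t then equals the ordinary pooled t.
Genes with `fdr < 0.05` and fold change above 1.5 (the gate applied to the
log2 group-mean difference, i.e. the ratio of geometric means) define the
cluster's up-regulated program, against which the per-tier enrichment of
in-vitro consistent genes is reported.

### 1.3 Signature derivation and classification (`pam`)

The signature is a nearest-shrunken-centroid (PAM) model over the seed
genes. With class centroids `xbar_ik`, overall centroid `xbar_i`, pooled
within-class SD `s_i` (df `n - K`), fudge `s0 = median_i s_i`,
`m_k = sqrt(1/n_k - 1/n)` and priors `pi_k = n_k / n`:

    d_ik  = (xbar_ik - xbar_i) / (m_k (s_i + s0))
    d'_ik = sign(d_ik) max(|d_ik| - Delta, 0)
    xbar'_ik = xbar_i + m_k (s_i + s0) d'_ik
    delta_k(x) = sum_i (x_i - xbar'_ik)^2 / (s_i + s0)^2 - 2 log pi_k

Genes with some `d'_ik != 0` are the signature; a new tumor takes the class
with the smaller discriminant score, ties going to *high* so hypoxia is
flagged conservatively. The shrinkage amount Delta is chosen by stratified
10-fold cross validation over a 30-point grid on `[0, max |d_ik|]`; among
thresholds attaining the minimum held-out error count the **largest**
(sparsest signature) is chosen. Fold assignment is seeded; the fold count
drops to the smaller class size when needed. CV accuracy is reported as a
percentage with one decimal.

New cohorts are preprocessed exactly like the training data — log2 scale
plus per-cohort gene-median centering — before classification. This is the
package's documented cross-platform choice; additive per-gene platform
offsets are removed exactly by it, while differences in phenotype
prevalence between cohorts shift gene medians slightly and are the main
residual cross-cohort error source.

### 1.4 Survival and association analysis (`survival`, `assoc`)

All endpoints are administratively censored at five years; an event exactly
at the horizon counts (censoring applies strictly after it). Kaplan–Meier
estimation and the K-sample log-rank test are delegated to lifelines; Cox
proportional-hazards models are backed by the statsmodels PH regression,
which provides both Efron (default) and Breslow tie handling. Hazard ratios
carry Wald 95% CIs `exp(beta +/- 1.96 se)` and Wald p-values. Categorical
covariates expand against a declared reference level; rows with missing
covariates are excluded (complete-case) and counted. Two kinds of
degenerate coefficients are flagged non-estimable rather than reported:
constant columns (empty strata) and binary indicators whose positive or
negative group carries no events (monotone likelihood — the MLE diverges);
a fitted |log HR| > 15 is likewise flagged. Combining the hypoxia call with
a second binary signature yields four strata {LL, LH, HL, HH} (hypoxia
letter first), tested jointly by a 3-df log-rank and by a Cox model with
three indicators against the LL reference.

Association tests are the Pearson chi-square without continuity correction
(Yates optional for 2×2) and the Welch unequal-variance t test. The
literature-comparator classifier scores each tumor by the median expression
of a fixed gene panel and splits the cohort at its median (or quartile);
the boundary sample goes to *low*.

## 2. The synthetic study (`simulate`)

The generator emulates the study design end to end. Defaults describe a
desk-scale, well-powered study and are fixed; they are conditions, not
tuning knobs:

| parameter | default | meaning |
|---|---|---|
| `n_genes` | 2000 | gene universe (desk-scale stand-in for ~20k) |
| `n_cell_lines`, `n_replicates` | 7, 3 | paired experiments, triplicates |
| `n_core_hypoxia_genes` | 40 | program induced in every line |
| `n_partial_hypoxia_genes` | 60 | program induced in random line subsets |
| `induction_log2fc_range` | (2.5, 5.0) | 6–32-fold; canonical strong hypoxia targets |
| `baseline_logmean_distribution` | N(6.0, 1.5) | log2 mean counts after routine low-count filtering |
| `nb_dispersion_range` | U(0.01, 0.1) | cell-line biological replicates |
| `cohort_sizes` | (180, 130, 250) | training + two validation cohorts |
| `phenotype_prevalence` | 0.22 | latent high-hypoxia fraction |
| `tumor_effect_size` | (1.25, 0.25) | per-gene log2 shift in high tumors |
| `cohort_shift_sd` | 0.5 | additive per-gene platform offsets |
| `noise_sd` | 1.0 | residual log2 noise |
| `true_hr` | 2.5 | hazard ratio of high vs low phenotype |
| `second_hr` | 1.0 | hazard multiplier of the second signature |
| `baseline_hazard` | 0.10 / yr | exponential baseline |
| `second_signature_probs` | (0.48, 0.76) | P(second label high given phenotype) |

Counts are gamma-Poisson draws with per-sample library-size factors in
U(0.7, 1.4). Cohort expression is `baseline + cohort offset + program shift
× I[high] + noise`; the first cohort defines the reference platform (zero
offset). Survival is exponential with hazard
`baseline_hazard × true_hr^I[high] × second_hr^I[second high]`, censored by
the minimum of a U(2, 12)-year draw and a 10-year administrative cutoff
(the analysis then censors at 5 years). The second label's hazard
multiplier defaults to 1 so that `true_hr` is exactly the marginal
phenotype hazard ratio; the label is still prognostic marginally through
its association with the phenotype, mirroring how a genome-instability
signature co-varies with hypoxia. Down-regulation programs are off by
default. Every planted quantity is recorded in a ground-truth manifest.

**What the generator does not emulate**: read-level artifacts, mean–
variance trends in dispersion, correlated gene–gene noise, non-additive
batch effects, histologic-subtype covariate structure, or non-proportional
hazards. Passing tests therefore demonstrate that the pipeline recovers
planted structure under its own model assumptions, not that it is robust
to every failure mode of real cohorts.

## 3. Numerical choices

* IRLS: coefficient tolerance 1e-8, 50 iterations, linear predictor clipped
  to ±30; non-convergent genes flagged, never silently reported.
* Trigamma inversion: Newton iteration, relative tolerance 1e-10, with the
  standard large/small-argument closed-form starts.
* Dispersion floor 1e-8; trend fit falls back to gene-wise estimates when
  fewer than 10 informative genes exist.
* Cox convergence is delegated to the backend (up to 200 iterations);
  singular-Hessian failures surface as estimation errors.
* All randomness flows through named seeds (simulation seed; per-stage
  cluster/CV/Monte-Carlo seeds), so a rerun with the same configuration is
  bit-reproducible.
* Problem sizes in the test and acceptance suites (2,000–5,000 genes,
  cohorts of 130–300, 10 seeds per property) were chosen as the smallest
  sizes at which the calibration and recovery properties are stable.

## 4. Known limitations

* The NB Wald test with the gene-vs-trend maximum is conservative by
  construction; genuinely low-dispersion genes pay a small power price.
* PAM's class-prior term combined with the `(s_i + s0)^2` standardization
  makes classification of cohorts whose phenotype prevalence differs from
  training slightly biased toward the majority class; this is a property of
  the published classifier retained deliberately.
* The moderated-t module supports only the two-group contrast the analysis
  needs — no general design matrices, weights, or trend/robust variants.
* Multi-class (K > 2) centroids, competing risks, time-varying covariates
  and proportionality diagnostics are out of scope.
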