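# sigforge

Derive and validate a tumor-type-specific **hypoxia gene-expression
signature**, end to end: in-vitro seed-gene discovery across cell lines,
in-vivo phenotype discovery by clustering, shrunken-centroid signature
derivation with cross-validated gene selection, centroid classification of
independent cohorts, and prognostic validation by survival analysis.

## Who this is for

Tumor hypoxia drives treatment resistance and metastasis, and the
transcriptional response to low oxygen differs between tumor types, so a
signature derived in one tissue transfers poorly to another. `sigforge`
packages the standard derivation recipe for building a *de novo* signature
in a new tumor type — for bioinformaticians who have (a) paired
hypoxia/normoxia expression from a panel of cell lines and (b) one or more
patient cohorts with expression and time-to-event outcomes. A synthetic-data
generator with planted ground truth makes the whole pipeline testable
without any external data, and is how the package validates itself.

## The model at the core

Seed genes are those induced by hypoxia (`fdr < 0.05` and ≥ 2-fold, NB Wald
test) in **every** cell line. Tumors are K-means-clustered on median-
centered seed-gene expression into high- and low-hypoxia phenotypes, and a
**nearest shrunken centroid** (PAM) classifier is fitted on the seed genes:

```
d_ik  = (x̄_ik − x̄_i) / (m_k (s_i + s0)),   m_k = √(1/n_k − 1/n)
d′_ik = sign(d_ik) · max(|d_ik| − Δ, 0)
δ_k(x) = Σ_i (x_i − x̄′_ik)² / (s_i + s0)² − 2 log π_k
```

Soft-thresholding by Δ zeroes uninformative genes, so gene selection and
classification happen jointly; Δ is chosen by stratified 10-fold cross
validation (sparsest model among the error minima). A new tumor takes the
class whose shrunken centroid is closest in standardized squared distance.
Prognostic value is assessed by Kaplan–Meier/log-rank and Cox proportional
hazards (Efron ties, Wald CIs), censored at 5 years, optionally stratified
jointly with a second binary signature. See `docs/methods.md` for the full
model account.

## Worked example

```python
import sigforge as sf

# a synthetic study: 7 cell lines in triplicate + 3 tumor cohorts,
# with a planted hypoxia program and phenotype-linked survival
cfg = sf.SimulationConfig(rng_seed=1)
exps, cohorts, manifest = sf.simulate_study(cfg)

# 1. per-line differential expression, then cross-line consistency
de = {f"line{i}": sf.NBDifferentialExpression(e).fit() for i, e in enumerate(exps)}
report = sf.consistency_counts(de, cohort_universe=set(cohorts[0].gene_ids))
print(report.summary())

# 2. phenotype discovery in the training cohort
seed_expr = sf.log2_median_center(cohorts[0].expr.loc[report.seed_set])
phen = sf.cluster_phenotypes(seed_expr, n_restarts=1000, seed=1)

# 3. signature derivation with CV-chosen shrinkage
sig = sf.ShrunkenCentroid(seed_expr, phen.labels).fit(delta=None, seed=1)
print(sig.summary())

# 4. classify a validation cohort and test prognosis
val = cohorts[1]
pred = sig.classify(sf.log2_median_center(val.expr.loc[sig.gene_ids]))
rec = sf.censor_at(val.clinical.copy())          # censor at 5 years
rec["hypoxia"] = pred["label"]
cox = sf.CoxModel(rec, ["hypoxia"], reference_levels={"hypoxia": "low"}).fit()
print(cox.summary())
```

prints

```
Cross-cell-line hypoxia induction consistency
  up in >= 7 lines: 40   down in >= 7 lines: 0
  up in >= 6 lines: 49   down in >= 6 lines: 0
  up in >= 5 lines: 58   down in >= 5 lines: 0
  up in >= 4 lines: 68   down in >= 4 lines: 0
  seed genes (after filters): 40
Nearest shrunken centroid signature
  candidate genes: 40
  shrinkage Delta: 2.9291
  signature genes: 32
  class priors: high=0.261 low=0.739   fudge s0=1.0032
  10-fold CV accuracy at chosen Delta: 100.0
Cox proportional hazards (efron ties)  n=130, events=56, excluded=0
covariate                             HR            95% CI           p
hypoxia[high vs low]                2.40       (1.26-4.58)      0.0077
```

Reading the output: all 40 planted core-program genes — and no others —
were induced in all seven lines and became seeds; cross-validation kept a
32-gene signature at zero CV error; in the held-out cohort the tumors it
calls high-hypoxia relapse at 2.4 times the hazard of the rest (the planted
hazard ratio is 2.5), significant at p = 0.008.

The same analysis runs from the shell:

```
sigforge simulate --seed 1 --outdir data/
sigforge run --outdir results/          # or stage by stage:
sigforge de --counts data/counts_line0.tsv --samples data/samples_line0.csv --out de0.tsv
```

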