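# ebmkit

Event-based disease-progression modeling for high-dimensional tabular
biomarker data.

Chronic progressive diseases — neurodegeneration, many solid tumors —
accumulate molecular changes in a roughly monotone order, but most cohorts
are cross-sectional: each subject is observed once, at an unknown point
along the disease course. An **event-based model (EBM)** reconstructs the
ordering from such data by treating each biomarker as a single "event", a
transition from a pre-event (normal) distribution to a post-event
(abnormal) one, and inferring both the event ordering and each subject's
position (**stage**) along it. A mixture over orderings captures
phenotypic heterogeneity (**subtypes**).

`ebmkit` wraps that model in an end-to-end pipeline for practitioners
working with real omics matrices:

1. **Data readiness** — CSV/TSV/PSV ingestion with schema validation
   (`SubjectID`/`Outcome` metadata, exact-ID alignment), numeric coercion,
   a >20% missingness filter with kNN imputation (k = 5), and one-sided
   outlier capping at Q3 + 1.5·IQR per feature.
2. **Ensemble feature selection** — when p ≥ 100 features, three
   classifier families (LightGBM, logistic regression, random forest) ×
   five stratified CV folds vote on top-K importance lists; the stability
   score S(f) = appearances/15 drives retention (features with S > 0.5,
   with clipping/fallback rules), capped at 150 features.
3. **Subtype-and-stage inference** — per-biomarker two-component Gaussian
   mixtures define the event densities; EM alternates subject
   responsibilities r[n, k, s] with an ordering update (sort by expected
   event position, then likelihood-optimal contiguous cuts); a Metropolis
   sampler over stage-cluster assignments yields a positional-confidence
   matrix P[m, s] per subtype.
4. **Safeguards** — hard caps (150 features, 5 subtypes, 6 stages, cluster
   floor 5 with default 10), automatic merging of subtypes with < 10
   subjects, and visualization-only filtering of stages with < 3 subjects
   and a single outcome.
5. **Evaluation & reporting** — per-class precision/recall/F1 from 5-fold
   gradient-boosted-tree CV on the reduced features, ordinal accuracy with
   the distance-penalty reward R(i, j) = 1 − |i − j|/(K − 1), a
   row-normalized confusion matrix with a 75% mean-diagonal warning, a
   stratified χ² stage-separation test, and CSV/PNG exports of every
   result.

A first-class synthetic-cohort generator plants known subtype orderings
and stages, so every claim the pipeline makes can be checked against
ground truth without any external data.

## The model

For subtype k with stage-clusters C₁ᵏ, …, C_Sᵏ (a partition of the M
biomarkers), a subject at stage s has undergone exactly the events in
C₁ᵏ ∪ … ∪ C_sᵏ:

    log L(x | k, s) = Σ_{m ∈ C₁..C_s} log N(x_m; μ_post,m, σ_post,m)
                    + Σ_{m ∈ C_{s+1}..C_S} log N(x_m; μ_pre,m, σ_pre,m)

with s ∈ {0, …, S} (stage 0 = no events) under a uniform stage prior and
mixture weights π. The E-step computes r[n, k, s] ∝ π_k · L(x_n | k, s)
for all subjects, stages and subtypes — O(N·K·S·M) per iteration — and the
M-step re-sorts and re-cuts each subtype's ordering, O(K·M²). The MCMC
step re-evaluates the same likelihood per proposal.

## Worked example

Generate a small three-subtype proteomics-panel-like cohort and run the
pipeline:

```bash
ebmkit synth --preset ehbs_like --out cohort --seed 3
ebmkit run --data cohort/data.csv --meta cohort/meta.csv --out results_dir \
    --stages 4 --subtypes 3 --seed 42 \
    --outcome-order Control,AsymAD,AD
```

The run log (color-coded in the terminal) reports each stage:

```
[config] validated: EBMConfig(n_subtypes=3, n_stages=4, min_cluster=10, em_iters=100,
         mcmc_burnin=10000, mcmc_final=100000, seed=42, tol=0.0001), m_min=40
[readiness] 392 subjects x 71 features; dropped 0 features (>20% missing), imputed 0, capped 0 cells
[selection] scenario=skipped: kept 71 of 71 features (mean stability 1.000)
[model] EM converged in 7 iterations (loglik -40240.68)
[mcmc] acceptance rates 0.000, 0.000, 0.000
[done] total 27.9s; artifacts in scratch/results_dir
```

With only 71 features (< 100) selection is skipped and stability is
trivially 1.0. On this noiseless synthetic cohort the sampler accepts no
proposals — every perturbation of the recovered ordering is sharply worse —
and says so with a warning; on real data acceptance rates are the first
thing to check. `results_dir/` then contains `subject_assignments.csv`
(MAP subtype and stage per subject with its posterior probability),
`biomarker_stages.csv` (modal stage and confidence per biomarker and
subtype), `classification_report.csv`, `chi2_results.csv` (one χ²
goodness-of-fit row per subtype × outcome stratum; small p-values mean
stage occupancy deviates from uniform, i.e. staging separates outcomes),
and three figures: stage-distribution bars per subtype, a biomarker ×
(stage, outcome) heatmap, and the positional-confidence matrices whose
diagonal "staircase" indicates a well-identified ordering. Reruns with
the same seed produce byte-identical CSVs.

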