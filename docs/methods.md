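# Methods

This note records the model, the numerical choices, and the reasoning
behind the design decisions that were genuinely open, in enough detail
that a maintainer can predict what the code will do without reading it.

## The event model

Each biomarker m is modeled as undergoing a single event: its values are
drawn from a pre-event normal N(μ_pre,m, σ_pre,m) before the event and a
post-event normal N(μ_post,m, σ_post,m) after. Subtype k carries an
ordered partition of the M biomarkers into S contiguous *stage-clusters*;
a subject at stage s ∈ {0..S} has undergone exactly the events in
clusters 1..s. Stages are clusters of events rather than single events
because biological progression moves in modules (pathways of ~5–10
interacting molecules), and because cluster-level stages keep the
ordering search tractable at up to 150 biomarkers.

The observed-data likelihood mixes over subtypes (weights π) and stages
(uniform prior over the S+1 stage values). All likelihood work is done in
log space; a per-biomarker σ floor of 10⁻³ × (feature range) (10⁻⁶
absolutely) keeps densities finite for near-constant features.

Internally stage 0 ("no events yet") is a first-class state; reported
stages are 1-indexed 1..S with internal stage 0 reported as stage 1, so
user-facing tables and plots always show S stage values. The raw internal
stage is kept in the `InternalStage` column.

### Event-distribution estimation

Each biomarker gets a two-component univariate Gaussian mixture fitted
over the *whole* cohort. When the cohort has a designated baseline class
(the first label in the outcome order, by default), that class and the
most advanced class serve only to *orient* the two components: the
pre-event component is the one holding relatively more baseline than
advanced-class membership. Without any baseline class
(`has_baseline=False` in the pipeline; cohorts lacking healthy controls)
the lower-mean component is taken as pre-event.

Class moments alone (baseline mean/SD as pre, advanced as post) were
rejected as the primary estimator: outcome classes are not stage-pure —
baseline-class subjects at stage ≥ 1 have already passed the earliest
events — so class moments systematically inflate σ_pre for early-event
biomarkers (measured ~2.4 versus a true 1.0 on synthetic data) and
distort the likelihood enough to misorder events. The mixture fit is the
classic event-model recipe and is immune to this contamination; class
moments remain as a fallback when a biomarker's mixture collapses to two
identical components.

### EM

* **E-step**: responsibilities r[n, k, s] ∝ π_k · L(x_n | k, s) with the
  uniform stage prior, normalized per subject in log space (never NaN,
  including under severe underflow). Cost O(N·K·S·M) per iteration,
  computed as a dense (N×M)(M×(S+1)) product.
* **M-step**: for each subtype, every biomarker's placement value
  V[m, c] = expected complete-data log-likelihood of putting its event in
  cluster c is computed from two (M×(S+1)) matrix products; biomarkers
  are stably sorted by the softmax-expected position (stable sort: ties
  and zero-information posteriors keep the incumbent order) and the
  sorted sequence is cut into S contiguous clusters by a dynamic program
  over cut points that maximizes total placement value subject to the
  min-cluster floor — O(S·M²). A fixed near-equal-size cut was rejected:
  it cannot represent unequal true cluster sizes, and on synthetic data
  with known truth it provably destabilized EM (mixture weights drifted,
  assignment accuracy collapsed) because the forced boundary
  misplacements cascade through the responsibilities.
* **π update**: mean subtype responsibility, renormalized.
* **Convergence**: |Δ total log-likelihood| < `tol` (default 10⁻⁴) or
  `em_iters` (default 100).

### Initialization and restarts

Fits are deterministic given the seed. For K = 1 the biomarkers are
ordered by descending mean post-event evidence (events most subjects have
passed come first) and cut into equal clusters. For K > 1 the subject
split that seeds the mixture is searched over a small, fixed portfolio of
candidates — seeded k-means on the leading K+2 principal directions
(5 seeds), k-means on per-subject *evidence residuals* from a single-
ordering fit (3 seeds), and seeded random splits (3) — keeping the best
final log-likelihood. The residual construction exists because subtype
structure is precisely what a single ordering cannot explain; plain
k-means on the data splits subjects along the dominant progression axis
(stage), not subtype, and a single deterministic split was measured at
chance-level subtype recovery.

After EM, a greedy coordinate-ascent **polish** sweeps every biomarker
through every cluster placement (respecting the min-cluster floor),
accepting observed-data log-likelihood improvements, until a sweep
changes nothing (≤ 6 sweeps). This removes the sort-and-cut heuristic's
residual misplacements at negligible cost.

### MCMC positional confidence

A Metropolis sampler perturbs one subtype's cluster assignment at a time,
holding the other subtypes at their EM solutions: proposals move one
uniformly chosen biomarker to an adjacent cluster (only if the source
cluster stays at or above the min-cluster floor) or swap two biomarkers
between adjacent clusters; acceptance is min(1, exp(Δ log-likelihood)) on
the full observed-data likelihood. Burn-in samples (default 10,000) are
discarded and the retained samples (default 100,000) give
P[m, s] = frequency of biomarker m in cluster s — the
positional-confidence matrix — plus the best assignment visited, which
tests compare against exhaustive enumeration. Zero accepted proposals
over the whole run triggers a warning; on strongly separated (e.g. clean
synthetic) data this is expected — the likelihood surface is a needle —
while on real data it usually signals a degenerate fit.

The per-proposal likelihood is re-evaluated densely per subject, stage
and biomarker — the O(N·S·M) structure the model's runtime analysis is
built on — inside a numba-compiled kernel (the loop runs 10⁴–10⁵
iterations). The kernel's logsumexp skips terms below exp(−37), which is
exact at double precision.

### Runtime scaling benchmark

`ebmkit.benchmarks.runtime_scaling` times EM + MCMC on a simulated
cohort of N = 800 subjects with one subtype and **one stage-cluster per
biomarker** (S = M, min-cluster 1), the configuration under which the
per-evaluation cost N·S·M becomes N·M² and wall time is expected to grow
quadratically in M. With S fixed (the normal pipeline regime) cost is
linear in M; tying S to M reproduces the regime the complexity analysis
describes. The benchmark uses scaled-down iteration counts (EM 3,
burn-in 500, final 2,500, best of 3 repeats per point) — the scaling
exponent, not the absolute time, is the quantity of interest — and
excludes JIT compilation via a warm-up run. Measured log-log slope over
M ∈ {10, 25, 50, 100} is ≈ 1.6–1.7 (mild flattening at small M from the
O(N·S) logsumexp term and fixed per-iteration costs).

## Feature selection

K (the per-model top list size) = min(p, max(⌈0.05·p⌉, 3·U_max)): both
clauses are floors on candidate breadth and K can never exceed p. The
three classifiers are LightGBM (gain importance; ≤ 200 trees, depth ≤ 6),
logistic regression (|coefficient| on standardized inputs), and random
forest (mean impurity decrease; 200 trees), each fitted per stratified
fold with inverse-frequency sample weights. SMOTE oversampling (in-house,
seeded minority-class kNN interpolation, k = 5) is additionally applied
inside the training fold only when the minority class holds under 30% of
samples — weights alone suffice for mild imbalance. Fold i uses seed
base + i (42, 43, …).

Retention: features with S(f) > 0.5 (strict; 8/15 passes, 7/15 fails)
are trusted. If at least N_final qualify, the top N_final by stability
are kept (ties broken by mean importance rank, then name — this covers
the boundary case where exactly N_final qualify); if some but fewer
qualify, the set is clipped up to M_min = stages × min_cluster (never
past N_final); if none qualify, the top M_min by stability are taken.
Selection is skipped entirely below 100 features, with stability
reported as 1.0.

## Synthetic cohorts

The generator plants: a subtype per subject (configured proportions), a
true stage, and per-subtype stage partitions of the informative features;
informative feature m of subtype k reads N(δ·1[event passed], noise_sd)
and noise features N(0, noise_sd). Defaults δ = 5, noise_sd = 1 (the
effect-to-noise ratio the recovery properties are specified at);
missingness is MCAR.

Design choices that were open:

* **Stage distribution**: true stages are drawn from Binomial(S, ½)
  truncated to the subject's outcome band. Cohorts concentrate at
  intermediate stages, and subjects at stage 0 or S are
  subtype-uninformative *by construction* (they have passed no events or
  all of them, so every subtype ordering assigns them identical
  likelihood); a uniform draw would put 2/(S+1) of subjects in that
  ambiguous mass and bound subtype recovery accordingly.
* **Outcome bands**: the stage support {0..S} is split contiguously with
  remainder stages going to the *outer* bands (binary reduces to
  "stage ≤ S/2 ⇒ early class"); outcomes are assigned by exact class
  counts and the stage is drawn within the class's band, so preset
  compositions (e.g. 39/407) are matched exactly.
* **Subtype orderings**: subtype 0 keeps the canonical cluster order;
  each further subtype gets a distinct seeded permutation of the
  stage-clusters whose interior *prefix sets* differ from every earlier
  subtype's. A subject at stage s only reveals the set of events passed,
  so two orderings sharing a prefix set are indistinguishable at that
  stage; cyclic shifts witness that the constraint is satisfiable for
  K ≤ S, and rejection sampling falls back to mere distinctness if a
  constrained draw is exhausted.

What the generator does **not** emulate: count-distributed (e.g.
negative-binomial) expression, feature–feature correlation beyond the
planted event structure, batch effects, informative missingness, or
label noise. Passing recovery tests therefore demonstrates correctness
of the inference machinery under the stated model, not robustness to
real RNA-seq artifacts.

## Safeguards and evaluation

Caps: 150 features, 5 subtypes, 6 stages, min cluster ≥ 5 (default 10);
M_min = stages × min_cluster is the smallest feature count that can fill
every cluster. Subtypes with < 10 MAP subjects merge into the
highest-index subtype meeting the threshold (all-sparse collapses to the
most populated); the posterior is renormalized, not refitted — merging is
a reporting safeguard, and a refit under a different K is the user's
decision. Stages with < 3 subjects *and* a single outcome class are
dropped from plots only; model objects are untouched.

Ordinal accuracy uses R(i, j) = 1 − |i − j|/(K_c − 1) over classes
arranged by the user-supplied outcome order (for 3+ classes without an
explicit order it is skipped with a warning, since the formula needs an
ordinal arrangement). The normalized-confusion warning fires strictly
below a 75% mean diagonal; empty classes are excluded from the mean with
a note. The χ² stage-separation test is a goodness-of-fit of observed
stage counts against a uniform null per (subtype, outcome) stratum, with
the null spanning the stages *occupied by that subtype* (an unoccupied
stage carries no evidence either way); strata with < 2 occupied stages
are skipped, expected counts < 1 are flagged unreliable, and p-values
are reported raw (no multiple-testing correction).

## Determinism

Every stochastic component (fold splitting, classifier seeds, SMOTE,
k-means initialization, MCMC) derives from the single user seed; reruns
with the same seed produce byte-identical CSVs. Figures are written at
fixed size/DPI with fixed PNG metadata, and every figure has a companion
CSV with the plotted numbers so downstream checks never parse pixels.

## Problem sizes

Tests and the acceptance script run everything at reduced sizes chosen to
exercise the full code path: cohorts of 90–250 subjects, 6–120 features,
EM ≤ 40 iterations, MCMC 100–2,500 retained samples, and the benchmark
grid above. Defaults in the package (EM 100, burn-in 10,000, final
100,000) are the recommended analysis settings; a 392 × 71 three-subtype
run at defaults completes in under a minute on one CPU.

## Known limitations

* One event per biomarker with normal pre/post densities; no multi-level
  (z-score threshold) events and no longitudinal information.
* K and S are user choices; no information-criterion model selection.
* The EM ordering update is a heuristic ascent (sort + optimal cuts +
  greedy polish); the likelihood is multimodal and the restart portfolio,
  not a global guarantee, is what finds the dominant basin.
* Subtype merging renormalizes rather than refits.
* Subjects at internal stage 0 or S are intrinsically
  subtype-ambiguous; their MAP subtype follows the mixture weights.
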