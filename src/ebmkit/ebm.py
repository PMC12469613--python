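"""Subtype-and-stage event-based progression model (EM + MCMC).

The model treats each biomarker as undergoing a single "event": a transition
from a pre-event (normal) distribution N(mu_pre, sd_pre) to a post-event
(abnormal) distribution N(mu_post, sd_post).  Each subtype k carries its own
ordering of the M biomarkers, partitioned into S contiguous stage-clusters;
a subject at stage s (s in 0..S, where 0 means "no events yet") has undergone
exactly the events in clusters 1..s.  Subjects are soft-assigned to
(subtype, stage) pairs with a uniform stage prior and mixture weights pi.

Fitting alternates an E-step (assignment probabilities for all subjects,
stages and subtypes: O(N*K*S*M) per iteration) with an M-step that re-sorts
biomarkers by their responsibility-weighted expected event position and
re-partitions the sorted list into near-equal contiguous clusters.  A
Metropolis sampler over orderings then quantifies positional confidence:
the frequency with which each biomarker lands in each stage-cluster across
retained samples.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from sklearn.cluster import KMeans
from sklearn.mixture import GaussianMixture

from ._mcmc import mcmc_orderings
from .readiness import Cohort

__all__ = [
    "EBMConfig",
    "EventDistributions",
    "ProgressionModel",
    "PositionalConfidence",
    "fit_event_distributions",
    "stage_logliks",
    "subject_stage_loglik",
    "e_step",
    "m_step",
    "run_em",
    "run_mcmc",
    "assign_subjects",
    "fit_progression_model",
]

_LOG2PI = float(np.log(2.0 * np.pi))


@dataclass
class EBMConfig:
    """Model size and sampler budget.

    ``n_stages`` is the number of biomarker stage-clusters S (subject stages
    run 0..S internally and are reported 1..S); ``min_cluster`` is the floor
    on biomarkers per cluster.  Defaults for the sampler follow the validation
    harness sizes (burn-in 10,000 / final 100,000); tests and quick runs
    scale them down.
    """

    n_subtypes: int = 1
    n_stages: int = 4
    min_cluster: int = 10
    em_iters: int = 100
    mcmc_burnin: int = 10_000
    mcmc_final: int = 100_000
    seed: int = 42
    tol: float = 1e-4

    def __post_init__(self) -> None:
        if self.n_subtypes < 1 or self.n_stages < 1:
            raise ValueError("n_subtypes and n_stages must be at least 1")
        if self.min_cluster < 1:
            raise ValueError("min_cluster must be at least 1")


@dataclass
class EventDistributions:
    """Per-biomarker pre- and post-event normal densities."""

    mu_pre: np.ndarray
    sd_pre: np.ndarray
    mu_post: np.ndarray
    sd_post: np.ndarray
    mixture_fallback: bool = False

    def log_densities(self, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """(log pre-density, log post-density), each (n_subjects, M)."""
        lp = -0.5 * ((X - self.mu_pre) / self.sd_pre) ** 2 \
            - np.log(self.sd_pre) - 0.5 * _LOG2PI
        lq = -0.5 * ((X - self.mu_post) / self.sd_post) ** 2 \
            - np.log(self.sd_post) - 0.5 * _LOG2PI
        return lp, lq


@dataclass
class ProgressionModel:
    """Fitted orderings, mixture weights and subject posteriors."""

    config: EBMConfig
    dists: EventDistributions
    feature_names: list[str]
    orders: list[np.ndarray]          # per subtype: permutation of 0..M-1
    clusters: np.ndarray              # (K, M) cluster index 0..S-1 per biomarker
    pi: np.ndarray                    # (K,) mixture weights
    posterior: np.ndarray             # (N, K, S+1) responsibilities
    loglik_trace: list[float] = field(default_factory=list)
    warnings_: list[str] = field(default_factory=list)

    @property
    def n_stages(self) -> int:
        return self.config.n_stages

    @property
    def n_subtypes(self) -> int:
        return len(self.pi)

    def stage_partition(self, k: int) -> list[list[str]]:
        """Subtype k's stage-clusters as lists of biomarker names (stage 1..S)."""
        return [
            [self.feature_names[m] for m in np.where(self.clusters[k] == c)[0]]
            for c in range(self.config.n_stages)
        ]


@dataclass
class PositionalConfidence:
    """MCMC frequency with which each biomarker occupies each stage-cluster."""

    P: list[np.ndarray]               # per subtype: (M, S), rows sum to 1
    best_clusters: np.ndarray         # (K, M) best-likelihood sampled assignment
    best_loglik: float
    acceptance_rates: list[float]


def _sigma_floor(X: np.ndarray) -> np.ndarray:
    rng = X.max(axis=0) - X.min(axis=0)
    return np.maximum(1e-3 * rng, 1e-6)


def fit_event_distributions(
    cohort: Cohort,
    baseline_class: str | None = "auto",
    seed: int = 42,
) -> EventDistributions:
    """Estimate per-biomarker pre/post event densities.

    Each biomarker gets a two-component univariate Gaussian mixture fitted
    over the whole cohort — the classic event-model recipe, robust to the
    fact that no outcome class is stage-pure.  A designated baseline class
    (default: the first label in the cohort's outcome order, requiring at
    least 3 subjects) orients the components: the pre-event component is the
    one holding relatively more baseline-class than advanced-class
    membership.  Without a baseline (``baseline_class=None``, e.g. cohorts
    lacking healthy controls) the lower-mean component is taken as
    pre-event.  Degenerate mixtures fall back to baseline/advanced class
    moments when anchors exist.
    """
    X = cohort.X.to_numpy(dtype=float)
    floor = _sigma_floor(X)
    pre_mask = post_mask = None
    if baseline_class is not None:
        order = cohort.ordered_outcomes()
        base = order[0] if baseline_class == "auto" else baseline_class
        advanced = order[-1]
        y = cohort.outcomes.to_numpy()
        pre_mask = y == base
        post_mask = y == advanced
        if pre_mask.sum() < 3 or post_mask.sum() < 3 or base == advanced:
            warnings.warn(
                "anchor outcome classes have fewer than 3 subjects; "
                "orienting mixture components by their means instead",
                stacklevel=2,
            )
            pre_mask = post_mask = None
    return _mixture_distributions(X, floor, seed, pre_mask, post_mask)


def _mixture_distributions(
    X: np.ndarray,
    floor: np.ndarray,
    seed: int,
    pre_mask: np.ndarray | None = None,
    post_mask: np.ndarray | None = None,
) -> EventDistributions:
    M = X.shape[1]
    have_anchor = pre_mask is not None
    if have_anchor:
        anchor = (
            X[pre_mask].mean(axis=0),
            np.maximum(X[pre_mask].std(axis=0, ddof=1), floor),
            X[post_mask].mean(axis=0),
            np.maximum(X[post_mask].std(axis=0, ddof=1), floor),
        )
    mu_pre = np.empty(M)
    sd_pre = np.empty(M)
    mu_post = np.empty(M)
    sd_post = np.empty(M)
    for m in range(M):
        x = X[:, m : m + 1]
        if np.ptp(x) < 1e-12:
            mu_pre[m] = mu_post[m] = x[0, 0]
            sd_pre[m] = sd_post[m] = floor[m]
            continue
        gm = GaussianMixture(n_components=2, random_state=seed, n_init=1)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            gm.fit(x)
        means = gm.means_.ravel()
        sds = np.sqrt(gm.covariances_.ravel())
        if np.abs(means[0] - means[1]) < 1e-6 and have_anchor:
            # degenerate split: use class-anchored moments instead
            mu_pre[m], sd_pre[m] = anchor[0][m], anchor[1][m]
            mu_post[m], sd_post[m] = anchor[2][m], anchor[3][m]
            continue
        if have_anchor:
            # pre = the component enriched in baseline relative to advanced
            memb0 = gm.predict_proba(x)[:, 0]
            drift = memb0[pre_mask].mean() - memb0[post_mask].mean()
            pre = 0 if drift >= 0 else 1
        else:
            pre = int(np.argmin(means))
        post = 1 - pre
        mu_pre[m] = means[pre]
        mu_post[m] = means[post]
        sd_pre[m] = max(sds[pre], floor[m])
        sd_post[m] = max(sds[post], floor[m])
    return EventDistributions(mu_pre, sd_pre, mu_post, sd_post,
                              mixture_fallback=not have_anchor)


def _stage_indicator(clusters_k: np.ndarray, n_stages: int) -> np.ndarray:
    """B[m, s] = 1 if biomarker m's event has occurred by stage s (s in 0..S)."""
    return (clusters_k[:, None] < np.arange(n_stages + 1)[None, :]).astype(float)


def stage_logliks(
    log_pre: np.ndarray, log_post: np.ndarray,
    clusters_k: np.ndarray, n_stages: int,
) -> np.ndarray:
    """log L(x_n | subtype k, stage s) for all subjects and s in 0..S.

    A subject at stage s is evaluated under post-event densities for the
    biomarkers in clusters 1..s and pre-event densities for the rest.
    Computed as a dense (N x M)(M x (S+1)) product: O(N*S*M).
    """
    B = _stage_indicator(clusters_k, n_stages)
    return log_pre.sum(axis=1, keepdims=True) + (log_post - log_pre) @ B


def subject_stage_loglik(
    x: np.ndarray, clusters_k: np.ndarray, s: int, dists: EventDistributions
) -> float:
    """Single-subject log-likelihood at stage s under subtype k's partition."""
    lp, lq = dists.log_densities(x[None, :])
    n_stages = int(clusters_k.max()) + 1
    return float(stage_logliks(lp, lq, clusters_k, n_stages)[0, s])


def _joint_log(model_logliks: list[np.ndarray], pi: np.ndarray) -> np.ndarray:
    """(N, K, S+1) array of log pi_k - log(S+1) + log L(x | k, s)."""
    S1 = model_logliks[0].shape[1]
    with np.errstate(divide="ignore"):
        log_pi = np.log(pi)
    return np.stack(model_logliks, axis=1) + log_pi[None, :, None] - np.log(S1)


def e_step(
    log_pre: np.ndarray, log_post: np.ndarray,
    clusters: np.ndarray, pi: np.ndarray, n_stages: int,
) -> tuple[np.ndarray, float]:
    """Normalized responsibilities r[n, k, s] and the total data log-likelihood.

    r[n,k,s] is proportional to pi_k * L(x_n | k, s) with a uniform stage
    prior; everything is computed in log space so underflow never yields NaN.
    """
    lls = [stage_logliks(log_pre, log_post, clusters[k], n_stages)
           for k in range(len(pi))]
    joint = _joint_log(lls, pi)
    norm = logsumexp(joint, axis=(1, 2), keepdims=True)
    r = np.exp(joint - norm)
    return r, float(norm.sum())


def m_step(
    log_pre: np.ndarray, log_post: np.ndarray,
    posterior: np.ndarray, orders: list[np.ndarray],
    n_stages: int, min_cluster: int,
) -> tuple[list[np.ndarray], np.ndarray, np.ndarray, list[int]]:
    """Update orderings, partitions and mixture weights.

    For subtype k, each biomarker's expected event position comes from the
    responsibility-weighted complete-data log-likelihood of placing its event
    in each cluster c: V[m, c] = sum_s r[.,k,s] * (log pre if the event would
    still be pending at stage s, else log post).  The per-biomarker softmax
    of V gives a continuous expected position; biomarkers are stably
    re-sorted by it (ascending: early events first) and the sorted list is
    cut into S contiguous clusters at the cut points that maximize the total
    placement value, subject to the min-cluster floor — a dynamic program
    over (position, cluster) pairs, the O(K*M^2) trajectory-update step.
    Ties and zero-information posteriors keep the incumbent order.  Subtypes
    with under one subject-equivalent of responsibility are flagged for
    safeguard merging.
    """
    N, K, S1 = posterior.shape
    M = log_pre.shape[1]
    positions = np.arange(n_stages)
    new_orders: list[np.ndarray] = []
    clusters = np.empty((K, M), dtype=np.int64)
    empty: list[int] = []
    for k in range(K):
        r_k = posterior[:, k, :]                           # (N, S+1)
        if r_k.sum() < 1.0:
            empty.append(k)
        A = log_pre.T @ r_k                                # (M, S+1)
        B = log_post.T @ r_k
        # event in cluster c (stage c+1) is pending at stages s <= c
        cumA = np.cumsum(A, axis=1)
        cumB = np.cumsum(B, axis=1)
        V = cumA[:, :n_stages] + (cumB[:, -1:] - cumB[:, :n_stages])
        Vc = V - V.max(axis=1, keepdims=True)
        w = np.exp(Vc)
        score = (w @ positions) / w.sum(axis=1)
        order = orders[k]
        new_order = order[np.argsort(score[order], kind="stable")]
        new_orders.append(new_order)
        clusters[k] = _optimal_cuts(V[new_order], new_order, min_cluster)
    pi = posterior.sum(axis=(0, 2)) / N
    pi = pi / pi.sum()
    return new_orders, clusters, pi, empty


def _optimal_cuts(V_sorted: np.ndarray, order: np.ndarray,
                  min_cluster: int) -> np.ndarray:
    """Cut a sorted biomarker sequence into S contiguous clusters at the
    placement-value-maximizing boundaries (each cluster >= min_cluster).

    ``V_sorted[j, c]`` is the expected complete-data log-likelihood of
    placing the j-th sorted biomarker in cluster c.  Dynamic program over
    (cluster, end-position): O(S * M^2).
    """
    M, S = V_sorted.shape
    mc = min(min_cluster, M // S)     # infeasible floors relax to equal split
    cum = np.vstack([np.zeros(S), np.cumsum(V_sorted, axis=0)])  # (M+1, S)
    NEG = -np.inf
    best = np.full((S, M + 1), NEG)
    arg = np.zeros((S, M + 1), dtype=np.int64)
    hi0 = M - mc * (S - 1)
    best[0, mc : hi0 + 1] = cum[mc : hi0 + 1, 0]
    for c in range(1, S):
        lo_prev = mc * c
        hi = M - mc * (S - 1 - c)
        for j in range(mc * (c + 1), hi + 1):
            i_lo, i_hi = lo_prev, j - mc
            cand = best[c - 1, i_lo : i_hi + 1] \
                + (cum[j, c] - cum[i_lo : i_hi + 1, c])
            pick = int(np.argmax(cand))
            best[c, j] = cand[pick]
            arg[c, j] = i_lo + pick
    # backtrack boundaries
    z = np.empty(M, dtype=np.int64)
    j = M
    for c in range(S - 1, -1, -1):
        i = arg[c, j] if c > 0 else 0
        z[order[i:j]] = c
        j = i
    return z


def _equal_partition(order: np.ndarray, n_stages: int, M: int) -> np.ndarray:
    """Cut an ordering into S contiguous near-equal clusters (remainder early)."""
    base, rem = divmod(M, n_stages)
    sizes = [base + 1 if c < rem else base for c in range(n_stages)]
    z = np.empty(M, dtype=np.int64)
    pos = 0
    for c, size in enumerate(sizes):
        z[order[pos : pos + size]] = c
        pos += size
    return z


def _init_subtypes(X: np.ndarray, K: int, seed: int) -> np.ndarray:
    """Deterministic subtype seed groups: seeded k-means on the leading
    principal directions, clusters relabeled by ascending first-PC center.

    Subtype structure lives off the dominant progression axis, so a handful
    of components beyond the first is included.
    """
    if K == 1:
        return np.zeros(len(X), dtype=int)
    Xc = X - X.mean(axis=0)
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    n_pcs = int(min(K + 2, len(s)))
    signs = np.sign(Vt[np.arange(n_pcs), np.abs(Vt[:n_pcs]).argmax(axis=1)])
    pcs = U[:, :n_pcs] * s[:n_pcs] * signs   # fix the sign ambiguity
    km = KMeans(n_clusters=K, n_init=10, random_state=seed)
    labels = km.fit_predict(pcs)
    relabel = np.argsort(np.argsort(km.cluster_centers_[:, 0]))
    return relabel[labels]


def run_em(
    cohort: Cohort,
    cfg: EBMConfig,
    dists: EventDistributions | None = None,
    baseline_class: str | None = "auto",
) -> ProgressionModel:
    """Fit the progression model by EM.

    Initialization is deterministic given the seed: subjects are split into
    K groups by seeded k-means on their leading principal directions, each
    group's biomarkers are ordered by descending mean post-event evidence
    (events most subjects have undergone come first), and the ordering is cut
    into equal contiguous clusters.  EM then alternates responsibilities and
    ordering updates until the total log-likelihood moves less than ``tol``.
    With K > 1 subtypes the split-and-fit is restarted from a few different
    k-means seeds and the best-likelihood solution is kept (the mixture
    surface is multimodal; restarts are the standard remedy).
    """
    M = cohort.n_features
    K, S = cfg.n_subtypes, cfg.n_stages
    if M < S * cfg.min_cluster:
        raise ValueError(
            f"{M} biomarkers cannot fill {S} stages at min_cluster="
            f"{cfg.min_cluster}; need at least {S * cfg.min_cluster}"
        )
    if dists is None:
        dists = fit_event_distributions(cohort, baseline_class=baseline_class,
                                        seed=cfg.seed)
    X = cohort.X.to_numpy(dtype=float)
    log_pre, log_post = dists.log_densities(X)
    if K == 1:
        groups = np.zeros(len(X), dtype=int)
        model = _run_em_once(cohort, cfg, dists, log_pre, log_post, groups)
        return _polish(cohort, cfg, model, log_pre, log_post)
    best: ProgressionModel | None = None
    for groups in _candidate_splits(cohort, cfg, dists, X, log_pre, log_post):
        model = _run_em_once(cohort, cfg, dists, log_pre, log_post, groups)
        model = _polish(cohort, cfg, model, log_pre, log_post)
        if best is None or model.loglik_trace[-1] > best.loglik_trace[-1]:
            best = model
    return best


def _candidate_splits(cohort, cfg, dists, X, log_pre, log_post):
    """Initial subject splits for the K-subtype search.

    Combines seeded k-means on leading principal directions of the data,
    k-means on per-subject evidence residuals from a single-ordering fit
    (subtype structure is what that fit cannot explain), and seeded random
    splits — the mixture surface is multimodal and restart diversity is what
    finds the dominant basin.
    """
    K = cfg.n_subtypes
    splits = [_init_subtypes(X, K, cfg.seed + j) for j in range(5)]
    one = EBMConfig(
        n_subtypes=1, n_stages=cfg.n_stages, min_cluster=cfg.min_cluster,
        em_iters=min(cfg.em_iters, 25), seed=cfg.seed, tol=cfg.tol,
    )
    m1 = _run_em_once(cohort, one, dists, log_pre, log_post,
                      np.zeros(len(X), dtype=int))
    with np.errstate(over="ignore"):
        evid = 1.0 / (1.0 + np.exp(log_pre - log_post))
    B = _stage_indicator(m1.clusters[0], cfg.n_stages)
    resid = evid - m1.posterior[:, 0, :] @ B.T
    for j in range(3):
        km = KMeans(n_clusters=K, n_init=10, random_state=cfg.seed + j)
        splits.append(km.fit_predict(resid))
    rng = np.random.default_rng(cfg.seed)
    for _ in range(3):
        splits.append(rng.integers(0, K, size=len(X)))
    return splits


def _polish(
    cohort: Cohort, cfg: EBMConfig, model: ProgressionModel,
    log_pre: np.ndarray, log_post: np.ndarray, max_sweeps: int = 6,
) -> ProgressionModel:
    """Greedy coordinate ascent on the observed-data log-likelihood.

    Sweeps every biomarker through every stage-cluster placement (respecting
    the min-cluster floor) and keeps the best, one subtype at a time, until
    a sweep changes nothing.  EM's sort-and-cut M-step gets close; this
    removes its residual misplacements.
    """
    S, K = cfg.n_stages, cfg.n_subtypes
    D = log_post - log_pre
    pre_tot = log_pre.sum(axis=1)
    clusters = model.clusters.copy()
    pi = model.pi.copy()
    logprior = -np.log(S + 1.0)
    stages_arange = np.arange(S + 1)

    def stage_ll(z):
        return pre_tot[:, None] + D @ _stage_indicator(z, S)

    for _ in range(max_sweeps):
        changed = 0
        for k in range(K):
            lls = [stage_ll(clusters[kk]) for kk in range(K)]
            joint = _joint_log(lls, pi)
            if K > 1:
                others = [kk for kk in range(K) if kk != k]
                rest = logsumexp(joint[:, others, :], axis=(1, 2))
            else:
                rest = np.full(len(D), -np.inf)
            z = clusters[k]
            counts = np.bincount(z, minlength=S)
            Lk = lls[k]
            with np.errstate(divide="ignore"):
                log_pi_k = np.log(pi[k])
            for m in range(len(z)):
                if counts[z[m]] <= cfg.min_cluster:
                    continue
                Lbase = Lk - D[:, m : m + 1] * (z[m] < stages_arange)[None, :]
                best_c, best_v = z[m], None
                for c in range(S):
                    Lc = Lbase + D[:, m : m + 1] * (c < stages_arange)[None, :]
                    contrib = logsumexp(log_pi_k + logprior + Lc, axis=1)
                    v = float(np.logaddexp(rest, contrib).sum())
                    if best_v is None or v > best_v + 1e-7:
                        best_v, best_c = v, c
                if best_c != z[m]:
                    counts[z[m]] -= 1
                    counts[best_c] += 1
                    z[m] = best_c
                    Lk = stage_ll(z)
                    changed += 1
        posterior, _ = e_step(log_pre, log_post, clusters, pi, S)
        pi = posterior.sum(axis=(0, 2)) / len(D)
        pi = pi / pi.sum()
        if changed == 0:
            break
    posterior, ll = e_step(log_pre, log_post, clusters, pi, S)
    orders = [np.argsort(clusters[k], kind="stable") for k in range(K)]
    return ProgressionModel(
        config=cfg, dists=model.dists, feature_names=model.feature_names,
        orders=orders, clusters=clusters, pi=pi, posterior=posterior,
        loglik_trace=model.loglik_trace + [ll],
        warnings_=model.warnings_,
    )


def _run_em_once(
    cohort: Cohort, cfg: EBMConfig, dists: EventDistributions,
    log_pre: np.ndarray, log_post: np.ndarray, groups: np.ndarray,
) -> ProgressionModel:
    M = cohort.n_features
    K, S = cfg.n_subtypes, cfg.n_stages
    with np.errstate(over="ignore"):
        evid = 1.0 / (1.0 + np.exp(log_pre - log_post))
    feat_order_tiebreak = np.arange(M)
    orders = []
    clusters = np.empty((K, M), dtype=np.int64)
    for k in range(K):
        in_k = groups == k
        mean_evid = evid[in_k].mean(axis=0) if in_k.any() else evid.mean(axis=0)
        order = np.lexsort((feat_order_tiebreak, -mean_evid))
        orders.append(order)
        clusters[k] = _equal_partition(order, S, M)
    pi = np.bincount(groups, minlength=K).astype(float)
    pi = np.maximum(pi, 1.0)
    pi = pi / pi.sum()

    trace: list[float] = []
    model_warnings: list[str] = []
    for _ in range(cfg.em_iters):
        posterior, ll = e_step(log_pre, log_post, clusters, pi, S)
        if not np.isfinite(ll):
            raise FloatingPointError(
                "non-finite log-likelihood during EM; check input scaling"
            )
        trace.append(ll)
        orders, clusters, pi, empty = m_step(
            log_pre, log_post, posterior, orders, S, cfg.min_cluster
        )
        if empty:
            model_warnings.append(
                f"subtype(s) {empty} hold under one subject-equivalent of "
                "responsibility; consider fewer subtypes"
            )
        if len(trace) > 1 and abs(trace[-1] - trace[-2]) < cfg.tol:
            break
    posterior, ll = e_step(log_pre, log_post, clusters, pi, S)
    trace.append(ll)
    return ProgressionModel(
        config=cfg, dists=dists, feature_names=cohort.feature_names,
        orders=orders, clusters=clusters, pi=pi, posterior=posterior,
        loglik_trace=trace, warnings_=model_warnings,
    )


def run_mcmc(cohort: Cohort, model: ProgressionModel,
             cfg: EBMConfig | None = None) -> PositionalConfidence:
    """Metropolis sampling over stage-cluster assignments, one subtype at a time.

    Proposals move one uniformly chosen biomarker to an adjacent cluster
    (respecting the min-cluster floor) or swap two biomarkers between
    adjacent clusters; acceptance is min(1, exp(delta log-lik)) on the full
    observed-data likelihood, holding the other subtypes at their EM
    solutions.  Burn-in samples are discarded; the retained-sample frequency
    of biomarker m in cluster s is the positional confidence P[m, s].
    """
    cfg = cfg or model.config
    S, K = cfg.n_stages, model.n_subtypes
    X = cohort.X.to_numpy(dtype=float)
    log_pre, log_post = model.dists.log_densities(X)
    D = np.ascontiguousarray(log_post - log_pre)
    pre_tot = log_pre.sum(axis=1)
    lls = [stage_logliks(log_pre, log_post, model.clusters[k], S)
           for k in range(K)]
    with np.errstate(divide="ignore"):
        log_pi = np.log(model.pi)
    joint = _joint_log(lls, model.pi)

    P: list[np.ndarray] = []
    best_clusters = model.clusters.copy()
    best_ll = float(logsumexp(joint, axis=(1, 2)).sum())
    rates: list[float] = []
    rng = np.random.default_rng(cfg.seed)
    for k in range(K):
        others = [j for j in range(K) if j != k]
        if others:
            rest = logsumexp(joint[:, others, :], axis=(1, 2))
        else:
            rest = np.full(len(X), -np.inf)
        kernel_seed = int(rng.integers(0, 2**31 - 1))
        counts, best_z, best_ll_k, n_acc = mcmc_orderings(
            D, pre_tot, rest, model.clusters[k].copy(), S,
            cfg.min_cluster, cfg.mcmc_burnin, cfg.mcmc_final,
            float(log_pi[k]), kernel_seed,
        )
        rate = n_acc / max(cfg.mcmc_burnin + cfg.mcmc_final, 1)
        rates.append(rate)
        if rate == 0.0:
            warnings.warn(
                f"MCMC accepted no proposals for subtype {k}; "
                "the likelihood surface may be degenerate",
                stacklevel=2,
            )
        P.append(counts / max(cfg.mcmc_final, 1))
        if best_ll_k > best_ll:
            best_ll = float(best_ll_k)
            best_clusters = best_clusters.copy()
            best_clusters[k] = best_z
    return PositionalConfidence(
        P=P, best_clusters=best_clusters, best_loglik=best_ll,
        acceptance_rates=rates,
    )


def assign_subjects(model: ProgressionModel) -> pd.DataFrame:
    """Per-subject MAP subtype and stage with the posterior maximum.

    Ties break toward the lower stage, then the lower subtype index.
    Internal stage 0 (no events) is reported as stage 1, so reported stages
    run 1..S; subtypes are reported 1-indexed.
    """
    r = model.posterior                       # (N, K, S+1)
    N, K, S1 = r.shape
    # row-major argmax over (stage, subtype) picks lowest stage then subtype
    flat = r.transpose(0, 2, 1).reshape(N, -1)
    idx = flat.argmax(axis=1)
    stage = idx // K
    subtype = idx % K
    return pd.DataFrame(
        {
            "Subtype": subtype + 1,
            "Stage": np.maximum(stage, 1),
            "InternalStage": stage,
            "PosteriorProb": flat.max(axis=1),
        }
    )


def fit_progression_model(
    cohort: Cohort,
    cfg: EBMConfig,
    baseline_class: str | None = "auto",
) -> tuple[ProgressionModel, PositionalConfidence]:
    """Convenience wrapper: EM fit followed by MCMC positional confidence."""
    model = run_em(cohort, cfg, baseline_class=baseline_class)
    conf = run_mcmc(cohort, model, cfg)
    return model, conf
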