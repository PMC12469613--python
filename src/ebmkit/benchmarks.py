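"""Runtime-scaling benchmark of the core inference engine.

Replicates the validation harness of the upstream complexity study: a
simulated cohort of N = 800 subjects, one subtype, and one stage-cluster per
biomarker (S = M, min_cluster = 1), timing EM + MCMC as the biomarker count
M grows.  With stages tied to biomarkers the per-iteration likelihood
evaluation is O(N*M^2), so wall time should scale roughly quadratically in
M; the measured log-log slope is the headline number.  Iteration counts here
are scaled down from the harness defaults so the benchmark completes at desk
scale without changing the scaling shape.
"""

from __future__ import annotations

import time

import numpy as np
import pandas as pd

from .ebm import EBMConfig, EventDistributions, run_em, run_mcmc
from .readiness import Cohort

__all__ = ["benchmark_cohort", "runtime_scaling", "loglog_slope"]


def benchmark_cohort(n_biomarkers: int, n_subjects: int = 800,
                     effect: float = 5.0, seed: int = 42) -> Cohort:
    """One-event-per-stage synthetic cohort: biomarker m flips at stage m+1."""
    rng = np.random.default_rng(seed)
    stage = rng.integers(0, n_biomarkers + 1, size=n_subjects)
    X = rng.normal(0.0, 1.0, size=(n_subjects, n_biomarkers))
    X += effect * (np.arange(n_biomarkers)[None, :] < stage[:, None])
    ids = [f"S{i:04d}" for i in range(n_subjects)]
    data = pd.DataFrame(X, columns=[f"F{m:03d}" for m in range(n_biomarkers)],
                        index=pd.Index(ids, name="SubjectID"))
    meta = pd.DataFrame({
        "SubjectID": ids,
        "Outcome": np.where(stage <= n_biomarkers // 2, "Early", "Late"),
    })
    return Cohort(X=data, meta=meta, outcome_order=["Early", "Late"])


def runtime_scaling(
    m_values: tuple[int, ...] = (10, 25, 50, 100),
    n_subjects: int = 800,
    em_iters: int = 3,
    mcmc_burnin: int = 500,
    mcmc_final: int = 2500,
    seed: int = 42,
    repeats: int = 3,
) -> pd.DataFrame:
    """Wall time of EM + MCMC across biomarker counts, S = M, K = 1.

    A small warm-up run first triggers JIT compilation so compile time never
    contaminates the measurements; each point takes the best of ``repeats``
    runs to suppress scheduler jitter.
    """
    _run_once(4, 50, 2, 20, 40, seed)  # warm-up: compile the sampler
    rows = []
    for m in m_values:
        elapsed = min(
            _run_once(m, n_subjects, em_iters, mcmc_burnin, mcmc_final, seed)
            for _ in range(repeats)
        )
        rows.append({"M": m, "seconds": elapsed})
    return pd.DataFrame(rows)


def _run_once(m: int, n_subjects: int, em_iters: int, burnin: int,
              final: int, seed: int) -> float:
    cohort = benchmark_cohort(m, n_subjects, seed=seed)
    # known event densities: the cohort is built from unit-variance shifts
    dists = EventDistributions(
        mu_pre=np.zeros(m), sd_pre=np.ones(m),
        mu_post=np.full(m, 5.0), sd_post=np.ones(m),
    )
    cfg = EBMConfig(
        n_subtypes=1, n_stages=m, min_cluster=1, em_iters=em_iters,
        mcmc_burnin=burnin, mcmc_final=final, seed=seed,
    )
    t0 = time.perf_counter()
    model = run_em(cohort, cfg, dists=dists)
    run_mcmc(cohort, model, cfg)
    return time.perf_counter() - t0


def loglog_slope(table: pd.DataFrame) -> float:
    """Least-squares slope of log(seconds) against log(M)."""
    return float(np.polyfit(np.log(table["M"]), np.log(table["seconds"]), 1)[0])
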