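"""Hard caps, soft defaults and post-fit safeguards against overparameterization.

The progression model is easy to over-specify: too many features make the
ordering search intractable, too many subtypes fragment small cohorts, and
too many stages produce sparsely populated bins.  This module enforces the
framework's bounds (150 features, 5 subtypes, 6 stages, minimum cluster size
5 with a default of 10), merges sparsely populated subtypes into the last
adequately populated one, and filters near-empty single-outcome stages out
of visualizations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ebm import EBMConfig, PositionalConfidence, ProgressionModel, assign_subjects

__all__ = [
    "ConfigError",
    "GuardedRunPlan",
    "MAX_FEATURES",
    "MAX_SUBTYPES",
    "MAX_STAGES",
    "MIN_CLUSTER_FLOOR",
    "validate_config",
    "merge_sparse_subtypes",
    "filter_sparse_stages",
]

MAX_FEATURES = 150
MAX_SUBTYPES = 5
MAX_STAGES = 6
MIN_CLUSTER_FLOOR = 5
MIN_CLUSTER_DEFAULT = 10

#: subtypes with fewer MAP-assigned subjects than this get merged away
SPARSE_SUBTYPE_THRESHOLD = 10


class ConfigError(ValueError):
    """A user configuration value violates a framework bound."""


@dataclass
class GuardedRunPlan:
    """Validated model configuration plus derived feature requirements."""

    ebm: EBMConfig
    max_features: int
    m_min: int                      # minimum features: stages * min_cluster
    warnings: list[str] = field(default_factory=list)


def validate_config(
    stages: int = 4,
    subtypes: int = 1,
    min_cluster: int | None = None,
    max_features: int = MAX_FEATURES,
    em_iters: int = 100,
    mcmc_burnin: int = 10_000,
    mcmc_final: int = 100_000,
    seed: int = 42,
    tol: float = 1e-4,
) -> GuardedRunPlan:
    """Check user configuration against the framework's hard bounds.

    Every violation raises a :class:`ConfigError` naming the allowed bound;
    ``min_cluster`` defaults to 10 when unset.  The plan records
    ``m_min = stages * min_cluster``, the smallest feature count that can
    meaningfully fill every stage-cluster.
    """
    if not 1 <= subtypes <= MAX_SUBTYPES:
        raise ConfigError(
            f"subtypes={subtypes} is outside the allowed range 1..{MAX_SUBTYPES}"
        )
    if not 1 <= stages <= MAX_STAGES:
        raise ConfigError(
            f"stages={stages} is outside the allowed range 1..{MAX_STAGES}"
        )
    if min_cluster is None:
        min_cluster = MIN_CLUSTER_DEFAULT
    if min_cluster < MIN_CLUSTER_FLOOR:
        raise ConfigError(
            f"min_cluster={min_cluster} is below the required floor of "
            f"{MIN_CLUSTER_FLOOR}"
        )
    if not 1 <= max_features <= MAX_FEATURES:
        raise ConfigError(
            f"max_features={max_features} exceeds the hard cap of {MAX_FEATURES}"
        )
    ebm = EBMConfig(
        n_subtypes=subtypes, n_stages=stages, min_cluster=min_cluster,
        em_iters=em_iters, mcmc_burnin=mcmc_burnin, mcmc_final=mcmc_final,
        seed=seed, tol=tol,
    )
    m_min = stages * min_cluster
    plan = GuardedRunPlan(ebm=ebm, max_features=max_features, m_min=m_min)
    if m_min > max_features:
        raise ConfigError(
            f"stages*min_cluster={m_min} exceeds max_features={max_features}; "
            "reduce stages or the minimum cluster size"
        )
    return plan


def merge_sparse_subtypes(
    model: ProgressionModel,
    confidence: PositionalConfidence | None = None,
    threshold: int = SPARSE_SUBTYPE_THRESHOLD,
) -> tuple[ProgressionModel, PositionalConfidence | None, list[str]]:
    """Merge subtypes with fewer than ``threshold`` MAP-assigned subjects.

    Sparse subtypes donate their subjects and mixture mass to the last
    (highest-index) subtype meeting the threshold; when every subtype is
    sparse the model collapses to a single subtype (the most populated one,
    ties toward the higher index).  The posterior is renormalized, not
    refitted.  Returns the merged model, the matching positional-confidence
    subset and the warnings issued.
    """
    assignments = assign_subjects(model)
    counts = np.bincount(assignments["Subtype"] - 1, minlength=model.n_subtypes)
    sparse = [k for k in range(model.n_subtypes) if counts[k] < threshold]
    if not sparse:
        return model, confidence, []
    keep = [k for k in range(model.n_subtypes) if counts[k] >= threshold]
    warnings_ = []
    if keep:
        target = keep[-1]
        warnings_.append(
            f"subtype(s) {[k + 1 for k in sparse]} held fewer than {threshold} "
            f"subjects and were merged into subtype {target + 1}"
        )
    else:
        # every subtype sparse: collapse to the most populated one
        target = int(np.flatnonzero(counts == counts.max())[-1])
        keep = [target]
        sparse = [k for k in range(model.n_subtypes) if k != target]
        warnings_.append(
            f"all subtypes held fewer than {threshold} subjects; "
            f"collapsed to a single subtype (was subtype {target + 1})"
        )
    posterior = model.posterior.copy()
    pi = model.pi.copy()
    for k in sparse:
        posterior[:, target, :] += posterior[:, k, :]
        pi[target] += pi[k]
    posterior = posterior[:, keep, :]
    pi = pi[keep]
    merged = ProgressionModel(
        config=EBMConfig(
            n_subtypes=len(keep), n_stages=model.config.n_stages,
            min_cluster=model.config.min_cluster,
            em_iters=model.config.em_iters,
            mcmc_burnin=model.config.mcmc_burnin,
            mcmc_final=model.config.mcmc_final,
            seed=model.config.seed, tol=model.config.tol,
        ),
        dists=model.dists, feature_names=model.feature_names,
        orders=[model.orders[k] for k in keep],
        clusters=model.clusters[keep], pi=pi / pi.sum(), posterior=posterior,
        loglik_trace=list(model.loglik_trace),
        warnings_=model.warnings_ + warnings_,
    )
    merged_conf = None
    if confidence is not None:
        merged_conf = PositionalConfidence(
            P=[confidence.P[k] for k in keep],
            best_clusters=confidence.best_clusters[keep],
            best_loglik=confidence.best_loglik,
            acceptance_rates=[confidence.acceptance_rates[k] for k in keep],
        )
    return merged, merged_conf, warnings_


def filter_sparse_stages(assignments: pd.DataFrame) -> list[int]:
    """Stages retained for visualization.

    A stage is dropped from plots if and only if it holds fewer than three
    subjects AND only a single outcome class; the fitted model is untouched.
    Expects columns ``Stage`` and ``Outcome``.
    """
    retained = []
    for stage, grp in assignments.groupby("Stage"):
        if len(grp) < 3 and grp["Outcome"].nunique() == 1:
            continue
        retained.append(int(stage))
    return sorted(retained)
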