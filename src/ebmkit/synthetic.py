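"""Synthetic cohort generator with planted progression structure.

Generates biomarker matrices whose informative features undergo a monotone
mean shift at a planted stage along a latent progression, per subtype, so
that every pipeline component — readiness, selection, staging, evaluation —
can be exercised and its recovery quantified against known ground truth.
Cohort-shape presets emulate three archetypes: a large imbalanced binary
tumor/normal RNA-seq matrix, a three-ordered-outcome RNA-seq matrix without
healthy controls, and a small three-subtype targeted proteomics panel.

Subjects draw a true subtype (by the configured proportions) and a true
stage uniform within their outcome class's stage band; informative feature m
of subtype k then reads Normal(delta * 1[event passed], noise_sd) while pure
noise features read Normal(0, noise_sd).  Missingness is MCAR.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["GeneratorSpec", "GroundTruth", "generate", "preset", "PRESETS"]

_OUTCOME_LABELS = {
    "binary_case_control": ["Normal", "Tumor"],
    "ordered_three_class": ["Localized", "Invasive", "Metastatic"],
    "three_class_with_control": ["Control", "AsymAD", "AD"],
}


@dataclass
class GeneratorSpec:
    """Shape and signal parameters of a synthetic cohort.

    ``effect_size`` is the post-event mean shift in pre-event SD units
    (pre-event values are Normal(0, noise_sd)); ``outcome_props`` gives the
    class composition (earliest class first) and defaults to balanced.
    """

    n_subjects: int = 200
    n_features: int = 100
    n_informative: int = 40
    n_subtypes: int = 1
    n_stages: int = 4
    effect_size: float = 5.0
    noise_sd: float = 1.0
    missing_rate: float = 0.0
    outcome_scheme: str = "binary_case_control"
    outcome_props: tuple[float, ...] | None = None
    subtype_props: tuple[float, ...] | None = None
    seed: int = 42

    def __post_init__(self) -> None:
        if self.outcome_scheme not in _OUTCOME_LABELS:
            raise ValueError(
                f"unknown outcome_scheme {self.outcome_scheme!r}; choose from "
                f"{sorted(_OUTCOME_LABELS)}"
            )
        if self.n_informative > self.n_features:
            raise ValueError("n_informative cannot exceed n_features")
        if self.n_informative < 2 * self.n_stages:
            raise ValueError(
                f"need at least {2 * self.n_stages} informative features for "
                f"{self.n_stages} stages (2 per stage-cluster)"
            )
        if self.effect_size < 0:
            raise ValueError("effect_size must be nonnegative")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must be in [0, 1)")

    @property
    def outcome_labels(self) -> list[str]:
        return _OUTCOME_LABELS[self.outcome_scheme]


@dataclass
class GroundTruth:
    """Planted truth: per-subject subtype/stage, per-feature roles and clusters."""

    subtype: np.ndarray               # (n,) 0-based
    stage: np.ndarray                 # (n,) in 0..S
    informative: np.ndarray           # (p,) bool
    clusters: np.ndarray              # (K, p) cluster 0..S-1, -1 for noise
    outcome: np.ndarray = field(default=None)  # (n,) labels


def _prefix_sets(perm: np.ndarray, n_stages: int) -> set[frozenset]:
    """Interior-stage prefix sets of a cluster ordering: for each stage
    s = 1..S-1, the set of base clusters whose events have occurred."""
    order = np.argsort(perm)            # base clusters in event order
    return {frozenset(order[:s].tolist()) for s in range(1, n_stages)}


def _largest_remainder_counts(n: int, props: np.ndarray) -> np.ndarray:
    raw = props * n
    counts = np.floor(raw).astype(int)
    short = n - counts.sum()
    order = np.argsort(-(raw - counts))
    counts[order[:short]] += 1
    return counts


def _stage_bands(n_stages: int, n_classes: int) -> list[np.ndarray]:
    """Split the stage support {0..S} into contiguous ordered class bands.

    Remainder stages go to the outermost bands first, so interior classes
    get the narrower bands (e.g. S = 4, 3 classes -> {0,1}, {2}, {3,4});
    for two classes this reduces to "stage <= S/2 is the early class".
    """
    support = np.arange(n_stages + 1)
    base, rem = divmod(len(support), n_classes)
    sizes = np.full(n_classes, base)
    outer_first = []
    lo, hi = 0, n_classes - 1
    while lo <= hi:
        outer_first.append(lo)
        if hi != lo:
            outer_first.append(hi)
        lo, hi = lo + 1, hi - 1
    for j in outer_first[:rem]:
        sizes[j] += 1
    edges = np.concatenate([[0], np.cumsum(sizes)])
    return [support[edges[c]:edges[c + 1]] for c in range(n_classes)]


def _stage_weights(band: np.ndarray, n_stages: int) -> np.ndarray:
    """Binomial(S, 1/2) prior restricted to a band: cohorts concentrate at
    intermediate stages; extremes (no events / all events) are rare."""
    w = stats.binom.pmf(band, n_stages, 0.5)
    return w / w.sum()


def generate(
    spec: GeneratorSpec, out_dir: str | Path | None = None
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Draw a cohort; optionally write ``data.csv`` and ``meta.csv``.

    Returns the data table (SubjectID + features), the metadata table
    (SubjectID, Outcome) and the planted ground truth.  Identical specs give
    identical outputs.
    """
    rng = np.random.default_rng(spec.seed)
    n, p, S, K = (spec.n_subjects, spec.n_features, spec.n_stages,
                  spec.n_subtypes)
    labels = spec.outcome_labels
    n_classes = len(labels)
    out_props = np.asarray(
        spec.outcome_props if spec.outcome_props is not None
        else np.full(n_classes, 1 / n_classes)
    )
    sub_props = np.asarray(
        spec.subtype_props if spec.subtype_props is not None
        else np.full(K, 1 / K)
    )
    if abs(sub_props.sum() - 1) > 1e-8 or abs(out_props.sum() - 1) > 1e-8:
        raise ValueError("outcome_props and subtype_props must each sum to 1")

    out_counts = _largest_remainder_counts(n, out_props)
    outcome_idx = rng.permutation(np.repeat(np.arange(n_classes), out_counts))
    sub_counts = _largest_remainder_counts(n, sub_props)
    subtype = rng.permutation(np.repeat(np.arange(K), sub_counts))
    bands = _stage_bands(S, n_classes)
    weights = [_stage_weights(band, S) for band in bands]
    stage = np.array(
        [rng.choice(bands[c], p=weights[c]) for c in outcome_idx]
    )

    informative = np.zeros(p, dtype=bool)
    informative[: spec.n_informative] = True
    base_clusters = np.full(p, -1, dtype=int)
    info_idx = np.flatnonzero(informative)
    for c, chunk in enumerate(np.array_split(info_idx, S)):
        base_clusters[chunk] = c
    clusters = np.full((K, p), -1, dtype=int)
    # disjoint orderings across subtypes: subtype 0 keeps the canonical
    # cluster order, later subtypes get distinct seeded permutations of it
    perm_rng = np.random.default_rng(spec.seed + 104729)
    perms = [np.arange(S)]
    attempts = 0
    while len(perms) < K:
        cand = perm_rng.permutation(S)
        attempts += 1
        if any(np.array_equal(cand, q) for q in perms):
            continue
        # a subject at stage s only reveals the SET of clusters passed by s;
        # subtypes are identifiable at every interior stage iff their prefix
        # sets all differ, so reject orderings that share any prefix set
        # (cyclic shifts witness feasibility for K <= S; relax if exhausted)
        if attempts < 1000 and any(
            _prefix_sets(cand, S) & _prefix_sets(q, S) for q in perms
        ):
            continue
        perms.append(cand)
    for k in range(K):
        clusters[k, info_idx] = perms[k][base_clusters[info_idx]]

    X = rng.normal(0.0, spec.noise_sd, size=(n, p))
    shift = spec.effect_size * spec.noise_sd
    for k in range(K):
        in_k = subtype == k
        if not in_k.any():
            continue
        # event passed when the feature's cluster index < subject stage
        passed = clusters[k][None, :] < stage[in_k, None]
        passed &= informative[None, :]
        X[in_k] += shift * passed

    if spec.missing_rate > 0:
        mask = rng.random((n, p)) < spec.missing_rate
        X[mask] = np.nan

    ids = [f"S{i + 1:04d}" for i in range(n)]
    feats = [f"F{j + 1:05d}" for j in range(p)]
    data = pd.DataFrame(X, columns=feats)
    data.insert(0, "SubjectID", ids)
    meta = pd.DataFrame(
        {"SubjectID": ids, "Outcome": [labels[c] for c in outcome_idx]}
    )
    truth = GroundTruth(
        subtype=subtype, stage=stage, informative=informative,
        clusters=clusters, outcome=np.array([labels[c] for c in outcome_idx]),
    )
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        data.to_csv(out_dir / "data.csv", index=False)
        meta.to_csv(out_dir / "meta.csv", index=False)
    return data, meta, truth


PRESETS: dict[str, dict] = {
    # large imbalanced binary tumor/normal bulk RNA-seq shape
    "coad_like": dict(
        n_subjects=446, n_features=5092, n_informative=60, n_subtypes=1,
        n_stages=4, outcome_scheme="binary_case_control",
        outcome_props=(39 / 446, 407 / 446),
    ),
    # three ordered outcomes, no healthy controls, bulk RNA-seq shape
    "blca_like": dict(
        n_subjects=343, n_features=5727, n_informative=60, n_subtypes=1,
        n_stages=5, outcome_scheme="ordered_three_class",
        outcome_props=(19 / 343, 207 / 343, 117 / 343),
    ),
    # small targeted proteomics panel with three subtypes
    "ehbs_like": dict(
        n_subjects=392, n_features=71, n_informative=71, n_subtypes=3,
        n_stages=4, outcome_scheme="three_class_with_control",
        outcome_props=(133 / 392, 130 / 392, 129 / 392),
    ),
}


def preset(name: str, seed: int = 42, **overrides) -> GeneratorSpec:
    """Named cohort-shape preset; overrides are applied on top."""
    if name not in PRESETS:
        raise ValueError(
            f"unknown preset {name!r}; available presets: {sorted(PRESETS)}"
        )
    params = {**PRESETS[name], "seed": seed, **overrides}
    return GeneratorSpec(**params)
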