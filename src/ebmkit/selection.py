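"""Ensemble stability-scored feature selection.

High-dimensional omics matrices (10^3-10^4 features) destabilize event-based
models, so the pipeline votes features in with an ensemble: three classifier
families (gradient-boosted trees, logistic regression, random forest) are each
trained on five stratified cross-validation folds, and a feature scores one
"appearance" for every (classifier, fold) pair whose top-K importance list
contains it.  The stability score S(f) = appearances / 15 drives retention:
features with S > 0.5 are trusted, with clipping/fallback rules guaranteeing
enough features reach the progression model.

Selection activates only when the feature count is at least 100; smaller
panels (e.g. targeted proteomics) pass through untouched with S = 1.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lightgbm import LGBMClassifier
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import NearestNeighbors
from sklearn.preprocessing import StandardScaler

from .readiness import Cohort

__all__ = [
    "SelectionConfig",
    "StabilityTable",
    "SelectionResult",
    "determine_k",
    "train_fold_rankings",
    "stability_scores",
    "select_features",
    "maybe_skip_selection",
]

#: total voting slots: 3 classifier families x 5 folds
N_CLASSIFIERS = 3
N_FOLDS = 5
N_SLOTS = N_CLASSIFIERS * N_FOLDS

#: hard cap on features entering the progression model
HARD_FEATURE_CAP = 150

#: below this feature count, selection is skipped entirely
ACTIVATION_THRESHOLD = 100

#: SMOTE kicks in only when the minority class holds less than this share
SMOTE_TRIGGER = 0.30


@dataclass
class SelectionConfig:
    """Knobs of the ensemble vote.

    ``u_max`` is the user's maximum final feature count (hard-capped at 150);
    ``top_k`` overrides the derived candidate-list size K when set.
    """

    u_max: int = HARD_FEATURE_CAP
    top_k: int | None = None
    base_seed: int = 42
    stability_threshold: float = 0.5
    n_folds: int = N_FOLDS

    def __post_init__(self) -> None:
        if not 1 <= self.u_max <= HARD_FEATURE_CAP:
            raise ValueError(
                f"u_max must be in [1, {HARD_FEATURE_CAP}], got {self.u_max}"
            )


@dataclass
class StabilityTable:
    """Per-feature appearance counts, stability scores and importance ranks."""

    features: list[str]
    appearances: np.ndarray          # int, [0, 15]
    mean_rank: np.ndarray            # mean importance rank across the 15 lists
    k: int

    @property
    def stability(self) -> np.ndarray:
        return self.appearances / N_SLOTS

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "feature": self.features,
                "appearances": self.appearances,
                "stability": self.stability,
                "mean_importance_rank": self.mean_rank,
            }
        )


@dataclass
class SelectionResult:
    """Ordered retained features plus which retention scenario fired."""

    selected: list[str]
    scenario: str                    # abundant | clipped | fallback | skipped
    mean_stability: float
    table: StabilityTable | None = None
    warnings: list[str] = field(default_factory=list)


def determine_k(p: int, u_max: int) -> int:
    """Candidate-list size K = min(p, max(ceil(0.05 p), 3 u_max)).

    Both clauses are floors on candidate breadth: 5% of the feature space, or
    three times the user's final budget to absorb model-specific ranking
    noise.  K can never exceed the feature count itself.
    """
    if p < 1:
        raise ValueError(f"feature count must be positive, got {p}")
    if not 1 <= u_max <= HARD_FEATURE_CAP:
        raise ValueError(f"u_max must be in [1, {HARD_FEATURE_CAP}], got {u_max}")
    return min(p, max(math.ceil(0.05 * p), 3 * u_max))


def _smote(X: np.ndarray, y: np.ndarray, rng: np.random.Generator,
           k: int = 5) -> tuple[np.ndarray, np.ndarray]:
    """Minimal SMOTE: oversample every minority class to the majority size by
    interpolating between minority samples and their nearest minority neighbours."""
    classes, counts = np.unique(y, return_counts=True)
    n_max = counts.max()
    parts_X, parts_y = [X], [y]
    for cls, count in zip(classes, counts):
        need = n_max - count
        if need == 0:
            continue
        Xc = X[y == cls]
        if len(Xc) < 2:
            parts_X.append(np.repeat(Xc, need, axis=0))
            parts_y.append(np.full(need, cls, dtype=y.dtype))
            continue
        nn = NearestNeighbors(n_neighbors=min(k + 1, len(Xc))).fit(Xc)
        _, idx = nn.kneighbors(Xc)
        base = rng.integers(0, len(Xc), size=need)
        pick = rng.integers(1, idx.shape[1], size=need)
        neighbor = idx[base, pick]
        lam = rng.random((need, 1))
        parts_X.append(Xc[base] + lam * (Xc[neighbor] - Xc[base]))
        parts_y.append(np.full(need, cls, dtype=y.dtype))
    return np.vstack(parts_X), np.concatenate(parts_y)


def _inverse_frequency_weights(y: np.ndarray) -> np.ndarray:
    classes, counts = np.unique(y, return_counts=True)
    w = {c: len(y) / (len(classes) * n) for c, n in zip(classes, counts)}
    return np.array([w[v] for v in y])


def _classifier_bank(seed: int) -> dict[str, object]:
    return {
        "gbt": LGBMClassifier(
            n_estimators=200, max_depth=6, num_leaves=31,
            importance_type="gain", random_state=seed, n_jobs=1, verbose=-1,
        ),
        "logreg": LogisticRegression(
            max_iter=2000, solver="lbfgs", random_state=seed,
        ),
        "rf": RandomForestClassifier(
            n_estimators=200, random_state=seed, n_jobs=1,
        ),
    }


def train_fold_rankings(
    cohort: Cohort, cfg: SelectionConfig
) -> dict[tuple[str, int], np.ndarray]:
    """Fit 3 classifiers x 5 stratified folds; return per-feature importances.

    Fold ``i`` uses seed ``base_seed + i`` (42, 43, ...).  Class imbalance is
    corrected with inverse-frequency sample weights; SMOTE oversampling is
    additionally applied inside the training fold when the minority class
    holds under 30% of samples.  Importances are gain for boosted trees,
    |coefficient| (on standardized inputs) for logistic regression, and mean
    impurity decrease for random forests.
    """
    X = cohort.X.to_numpy(dtype=float)
    y = cohort.outcomes.to_numpy()
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("feature selection needs at least two outcome classes")
    if counts.min() < cfg.n_folds:
        raise ValueError(
            f"smallest class has {counts.min()} subjects, fewer than "
            f"{cfg.n_folds} folds; use fewer folds or more data"
        )
    skf = StratifiedKFold(n_splits=cfg.n_folds, shuffle=True,
                          random_state=cfg.base_seed)
    rankings: dict[tuple[str, int], np.ndarray] = {}
    for fold, (train_idx, _) in enumerate(skf.split(X, y)):
        seed = cfg.base_seed + fold
        Xtr, ytr = X[train_idx], y[train_idx]
        minority_share = np.min(np.bincount(pd.factorize(ytr)[0])) / len(ytr)
        if minority_share < SMOTE_TRIGGER:
            Xtr, ytr = _smote(Xtr, ytr, np.random.default_rng(seed))
        weights = _inverse_frequency_weights(ytr)
        for name, clf in _classifier_bank(seed).items():
            if name == "logreg":
                scaler = StandardScaler()
                Xfit = scaler.fit_transform(Xtr)
            else:
                Xfit = Xtr
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                clf.fit(Xfit, ytr, sample_weight=weights)
            if name == "logreg":
                imp = np.abs(clf.coef_).mean(axis=0)
            else:
                imp = np.asarray(clf.feature_importances_, dtype=float)
            rankings[(name, fold)] = imp
    return rankings


def stability_scores(
    rankings: dict[tuple[str, int], np.ndarray],
    k: int,
    feature_names: list[str],
) -> StabilityTable:
    """Count top-K appearances across the 15 (classifier, fold) lists.

    Importance ties at the K boundary are broken by feature-name order so the
    appearance counts are reproducible.
    """
    p = len(feature_names)
    if k > p:
        raise ValueError(f"K={k} exceeds the feature count p={p}")
    name_order = np.argsort(np.argsort(np.asarray(feature_names, dtype=object)))
    appearances = np.zeros(p, dtype=int)
    rank_sum = np.zeros(p, dtype=float)
    for imp in rankings.values():
        # sort by (-importance, name); stable tie-break via lexsort
        order = np.lexsort((name_order, -imp))
        ranks = np.empty(p, dtype=float)
        ranks[order] = np.arange(1, p + 1)
        appearances[order[:k]] += 1
        rank_sum += ranks
    return StabilityTable(
        features=list(feature_names),
        appearances=appearances,
        mean_rank=rank_sum / max(len(rankings), 1),
        k=k,
    )


def _stability_order(table: StabilityTable) -> np.ndarray:
    """Indices sorted by descending S, then mean importance rank, then name."""
    names = np.asarray(table.features, dtype=object)
    name_order = np.argsort(np.argsort(names))
    return np.lexsort((name_order, table.mean_rank, -table.stability))


def select_features(
    table: StabilityTable,
    n_final: int,
    m_min: int,
    stability_threshold: float = 0.5,
) -> SelectionResult:
    """Apply the three-scenario retention rule.

    abundant: at least ``n_final`` features clear the stability threshold --
    keep the top ``n_final`` by stability.  clipped: some but fewer than
    ``n_final`` clear it -- keep them all, then clip in the next-most-stable
    features until the count reaches ``m_min`` (never exceeding ``n_final``).
    fallback: none clear it -- keep the top ``m_min`` by stability.
    """
    p = len(table.features)
    if m_min > p:
        raise ValueError(
            f"the model needs at least {m_min} features but only {p} exist; "
            "reduce stages or the minimum cluster size"
        )
    if m_min < 1:
        raise ValueError("m_min must be at least 1")
    order = _stability_order(table)
    stab = table.stability
    n_stable = int((stab > stability_threshold).sum())
    if n_stable >= n_final:
        scenario, n_keep = "abundant", n_final
    elif n_stable >= 1:
        scenario, n_keep = "clipped", min(max(n_stable, m_min), n_final)
    else:
        scenario, n_keep = "fallback", m_min
    keep = order[:n_keep]
    selected = [table.features[i] for i in keep]
    return SelectionResult(
        selected=selected,
        scenario=scenario,
        mean_stability=float(stab[keep].mean()),
        table=table,
    )


def maybe_skip_selection(
    cohort: Cohort,
    cfg: SelectionConfig,
    n_final: int | None = None,
    m_min: int = 1,
) -> SelectionResult:
    """Run ensemble selection, or pass all features through when p < 100.

    Small panels are kept intact with stability trivially 1.0 for every
    feature, mirroring how targeted assays need no reduction.
    """
    p = cohort.n_features
    if p < ACTIVATION_THRESHOLD:
        table = StabilityTable(
            features=cohort.feature_names,
            appearances=np.full(p, N_SLOTS, dtype=int),
            mean_rank=np.ones(p),
            k=p,
        )
        return SelectionResult(
            selected=list(cohort.feature_names),
            scenario="skipped",
            mean_stability=1.0,
            table=table,
        )
    n_final = cfg.u_max if n_final is None else min(n_final, cfg.u_max)
    k = cfg.top_k if cfg.top_k is not None else determine_k(p, cfg.u_max)
    rankings = train_fold_rankings(cohort, cfg)
    table = stability_scores(rankings, k, cohort.feature_names)
    return select_features(table, n_final=n_final, m_min=m_min,
                           stability_threshold=cfg.stability_threshold)
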