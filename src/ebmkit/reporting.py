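"""CSV and figure export of fitted models.

Everything the pipeline infers is externalized to a user directory: subject
and biomarker annotations as CSV, plus three figure families — stage
distributions by outcome, biomarker heatmaps by (stage, outcome), and
positional-confidence matrices.  Every figure gets a companion CSV with the
exact numbers plotted, so downstream checks never have to parse pixels, and
all outputs are byte-stable across same-seed reruns.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
import seaborn as sns

from .ebm import PositionalConfidence, ProgressionModel
from .readiness import Cohort

__all__ = [
    "export_annotations",
    "plot_stage_distribution",
    "plot_heatmap",
    "plot_positional_confidence",
]

_SAVEFIG = dict(dpi=120, metadata={"Software": "ebmkit"})


def _save(fig, path: Path) -> None:
    fig.savefig(path, **_SAVEFIG)
    plt.close(fig)


def export_annotations(
    out_dir: str | Path,
    cohort: Cohort,
    assignments: pd.DataFrame,
    confidence: PositionalConfidence,
    model: ProgressionModel,
) -> tuple[Path, Path]:
    """Write subject- and biomarker-level subtype/stage annotation CSVs.

    The subject table carries (SubjectID, Outcome, Subtype, Stage,
    PosteriorProb); the biomarker table carries one row per
    (biomarker, subtype) with the modal stage (ties toward the earlier
    stage) and the positional-confidence maximum.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    subj = pd.DataFrame(
        {
            "SubjectID": cohort.subject_ids,
            "Outcome": cohort.outcomes.to_numpy(),
            "Subtype": assignments["Subtype"].to_numpy(),
            "Stage": assignments["Stage"].to_numpy(),
            "PosteriorProb": assignments["PosteriorProb"].round(6).to_numpy(),
        }
    )
    subj_path = out_dir / "subject_assignments.csv"
    subj.to_csv(subj_path, index=False)

    rows = []
    for k, P in enumerate(confidence.P):
        modal = P.argmax(axis=1)          # first max = earlier stage on ties
        conf = P.max(axis=1)
        for m, name in enumerate(model.feature_names):
            rows.append(
                {
                    "Biomarker": name,
                    "Subtype": k + 1,
                    "ModalStage": int(modal[m]) + 1,
                    "Confidence": round(float(conf[m]), 6),
                }
            )
    bio_path = out_dir / "biomarker_stages.csv"
    pd.DataFrame(rows).to_csv(bio_path, index=False)
    return subj_path, bio_path


def plot_stage_distribution(
    out_dir: str | Path,
    assignments: pd.DataFrame,
    retained_stages: list[int],
    outcome_order: list[str],
) -> Path:
    """Grouped bars of subject counts per stage and outcome, one panel per subtype.

    Stages removed by sparse-stage filtering are absent.  A companion CSV
    (``stage_distribution.csv``) carries the plotted counts.
    """
    out_dir = Path(out_dir)
    df = assignments[assignments["Stage"].isin(retained_stages)]
    counts = (
        df.groupby(["Subtype", "Stage", "Outcome"], observed=True)
        .size()
        .reset_index(name="Count")
    )
    counts.to_csv(out_dir / "stage_distribution.csv", index=False)
    subtypes = sorted(assignments["Subtype"].unique())
    fig, axes = plt.subplots(
        1, len(subtypes), figsize=(4.5 * len(subtypes), 3.6),
        sharey=True, squeeze=False,
    )
    for ax, k in zip(axes[0], subtypes):
        sub = counts[counts["Subtype"] == k]
        grid = (
            sub.pivot_table(index="Stage", columns="Outcome", values="Count",
                            fill_value=0, aggfunc="sum")
            .reindex(retained_stages, fill_value=0)
            .reindex(columns=outcome_order, fill_value=0)
        )
        grid.plot.bar(ax=ax, width=0.8, legend=False)
        ax.set_title(f"Subtype {k}")
        ax.set_xlabel("Stage")
        ax.set_ylabel("Subjects")
    axes[0][-1].legend(title="Outcome", fontsize=8)
    fig.tight_layout()
    path = out_dir / "stage_distribution.png"
    _save(fig, path)
    return path


def plot_heatmap(
    out_dir: str | Path,
    cohort: Cohort,
    assignments: pd.DataFrame,
) -> Path:
    """Mean biomarker expression per (stage, outcome) cell, min-max scaled.

    Rows (biomarkers) are ordered by their mean in the baseline (first)
    outcome class; values are already capped upstream and are rescaled to
    [0, 1] per biomarker so no single high-expression feature dominates the
    colormap (red = high, blue = low).
    """
    out_dir = Path(out_dir)
    outcome_order = cohort.ordered_outcomes()
    baseline = outcome_order[0]
    base_mean = cohort.X[cohort.outcomes.to_numpy() == baseline].mean(axis=0)
    if not (cohort.outcomes == baseline).any():
        base_mean = cohort.X.mean(axis=0)
    row_order = base_mean.sort_values(ascending=False).index

    labels = assignments[["Stage", "Outcome"]].copy()
    labels.index = cohort.X.index
    cells = []
    col_names = []
    for outcome in outcome_order:
        for stage in sorted(assignments["Stage"].unique()):
            mask = ((labels["Outcome"] == outcome)
                    & (labels["Stage"] == stage)).to_numpy()
            if mask.any():
                cells.append(cohort.X[mask].mean(axis=0))
                col_names.append(f"{outcome}/S{stage}")
    grid = pd.concat(cells, axis=1)
    grid.columns = col_names
    grid = grid.loc[row_order]
    span = grid.max(axis=1) - grid.min(axis=1)
    scaled = grid.sub(grid.min(axis=1), axis=0).div(span.replace(0, 1), axis=0)
    scaled.to_csv(out_dir / "biomarker_heatmap.csv")
    fig, ax = plt.subplots(
        figsize=(1.2 + 0.45 * len(col_names), 2 + 0.11 * len(grid))
    )
    sns.heatmap(scaled, cmap="coolwarm", vmin=0, vmax=1, ax=ax,
                yticklabels=len(grid) <= 80, cbar_kws={"label": "scaled mean"})
    ax.set_xlabel("Outcome / Stage")
    fig.tight_layout()
    path = out_dir / "biomarker_heatmap.png"
    _save(fig, path)
    return path


def plot_positional_confidence(
    out_dir: str | Path,
    confidence: PositionalConfidence,
    model: ProgressionModel,
) -> Path:
    """Per-subtype positional-confidence matrices (biomarkers x stages).

    Rows are sorted by modal stage, then descending confidence, so an
    informative model shows the characteristic staircase of dark cells
    marching down the diagonal.  Companion CSV: ``positional_confidence.csv``.
    """
    out_dir = Path(out_dir)
    K = len(confidence.P)
    long_rows = []
    fig, axes = plt.subplots(
        1, K, figsize=(3.8 * K, 2 + 0.11 * len(model.feature_names)),
        squeeze=False,
    )
    for k, (ax, P) in enumerate(zip(axes[0], confidence.P)):
        modal = P.argmax(axis=1)
        conf = P.max(axis=1)
        order = np.lexsort((-conf, modal))
        names = [model.feature_names[m] for m in order]
        mat = pd.DataFrame(
            P[order], index=names,
            columns=[f"S{s + 1}" for s in range(P.shape[1])],
        )
        sns.heatmap(mat, cmap="Reds", vmin=0, vmax=1, ax=ax,
                    yticklabels=len(mat) <= 80, cbar=k == K - 1)
        ax.set_title(f"Subtype {k + 1}")
        for name, row in mat.iterrows():
            for col, v in row.items():
                long_rows.append(
                    {"Subtype": k + 1, "Biomarker": name, "Stage": col,
                     "Confidence": round(float(v), 6)}
                )
    fig.tight_layout()
    pd.DataFrame(long_rows).to_csv(
        out_dir / "positional_confidence.csv", index=False
    )
    path = out_dir / "positional_confidence.png"
    _save(fig, path)
    return path
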