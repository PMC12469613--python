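"""End-to-end orchestration: readiness -> selection -> guarded model -> reports.

``run_pipeline`` is the single entry point behind the CLI.  It chains every
stage with stage-labeled logging, applies the safeguards, and writes the
full artifact bundle (annotation CSVs, stability table, classification
report, chi-squared results, figures, run log) to the output directory.
Identical seeds yield byte-identical CSV outputs.
"""

from __future__ import annotations

import platform
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .ebm import ProgressionModel, PositionalConfidence, assign_subjects, \
    fit_event_distributions, run_em, run_mcmc
from .evaluation import EvalReport, chi2_stage_separation, classification_report
from .readiness import Cohort, ReadinessReport, prepare_cohort
from .reporting import (export_annotations, plot_heatmap,
                        plot_positional_confidence, plot_stage_distribution)
from .safeguards import (GuardedRunPlan, filter_sparse_stages,
                         merge_sparse_subtypes, validate_config)
from .selection import SelectionConfig, SelectionResult, maybe_skip_selection

__all__ = ["PipelineResult", "run_pipeline"]


@dataclass
class PipelineResult:
    """Everything a finished run produced, in memory and on disk."""

    cohort: Cohort
    readiness: ReadinessReport
    selection: SelectionResult
    model: ProgressionModel
    confidence: PositionalConfidence
    assignments: pd.DataFrame
    evaluation: EvalReport
    retained_stages: list[int]
    out_dir: Path | None
    warnings_: list[str] = field(default_factory=list)


def _log(messages: list[str], stage: str, text: str,
         echo=None) -> None:
    line = f"[{stage}] {text}"
    messages.append(line)
    if echo is not None:
        echo(line)


def run_pipeline(
    data_path: str | Path,
    meta_path: str | Path,
    out_dir: str | Path | None = None,
    *,
    stages: int = 4,
    subtypes: int = 1,
    min_cluster: int | None = None,
    max_features: int = 150,
    seed: int = 42,
    em_iters: int = 100,
    mcmc_burnin: int = 10_000,
    mcmc_final: int = 100_000,
    outcome_order: list[str] | None = None,
    has_baseline: bool = True,
    make_plots: bool = True,
    delimiter: str | None = None,
    echo=None,
) -> PipelineResult:
    """Run the full pipeline on a data/metadata file pair.

    ``outcome_order`` lists outcome labels from earliest to most advanced
    (needed for ordinal metrics with 3+ classes and to anchor the pre-event
    distributions); ``has_baseline=False`` switches the event-distribution
    fit to the per-biomarker mixture path for cohorts without healthy
    controls.  ``echo`` is an optional callable for live log lines.
    """
    t0 = time.perf_counter()
    log: list[str] = []
    timings: dict[str, float] = {}

    plan: GuardedRunPlan = validate_config(
        stages=stages, subtypes=subtypes, min_cluster=min_cluster,
        max_features=max_features, em_iters=em_iters,
        mcmc_burnin=mcmc_burnin, mcmc_final=mcmc_final, seed=seed,
    )
    _log(log, "config", f"validated: {plan.ebm}, m_min={plan.m_min}", echo)

    t = time.perf_counter()
    cohort, readiness = prepare_cohort(
        data_path, meta_path, outcome_order=outcome_order, delimiter=delimiter
    )
    timings["readiness"] = time.perf_counter() - t
    _log(log, "readiness",
         f"{cohort.n_subjects} subjects x {cohort.n_features} features; "
         f"dropped {len(readiness.dropped_features_missingness)} features "
         f"(>20% missing), imputed {len(readiness.imputed_features)}, "
         f"capped {readiness.capped_cells} cells", echo)

    t = time.perf_counter()
    sel_cfg = SelectionConfig(u_max=plan.max_features, base_seed=seed)
    selection = maybe_skip_selection(cohort, sel_cfg, m_min=plan.m_min)
    timings["selection"] = time.perf_counter() - t
    reduced = cohort.restrict_features(selection.selected)
    _log(log, "selection",
         f"scenario={selection.scenario}: kept {len(selection.selected)} of "
         f"{cohort.n_features} features "
         f"(mean stability {selection.mean_stability:.3f})", echo)

    t = time.perf_counter()
    dists = fit_event_distributions(
        reduced, baseline_class="auto" if has_baseline else None, seed=seed
    )
    model = run_em(reduced, plan.ebm, dists=dists)
    timings["em"] = time.perf_counter() - t
    _log(log, "model",
         f"EM converged in {len(model.loglik_trace) - 1} iterations "
         f"(loglik {model.loglik_trace[-1]:.2f})", echo)

    t = time.perf_counter()
    confidence = run_mcmc(reduced, model, plan.ebm)
    timings["mcmc"] = time.perf_counter() - t
    _log(log, "mcmc",
         "acceptance rates "
         + ", ".join(f"{r:.3f}" for r in confidence.acceptance_rates), echo)

    model, confidence, merge_warnings = merge_sparse_subtypes(model, confidence)
    for w in merge_warnings:
        _log(log, "safeguards", f"WARNING: {w}", echo)

    assignments = assign_subjects(model)
    assignments.insert(0, "SubjectID", cohort.subject_ids)
    assignments["Outcome"] = cohort.outcomes.to_numpy()
    retained = filter_sparse_stages(assignments)
    dropped = sorted(set(assignments["Stage"].unique()) - set(retained))
    if dropped:
        _log(log, "safeguards",
             f"WARNING: stage(s) {dropped} hidden from plots "
             "(<3 subjects, single outcome)", echo)

    t = time.perf_counter()
    evaluation = classification_report(reduced, seed=seed)
    evaluation.chi2 = chi2_stage_separation(assignments)
    timings["evaluation"] = time.perf_counter() - t
    for w in evaluation.warnings_:
        _log(log, "evaluation", f"WARNING: {w}", echo)

    result = PipelineResult(
        cohort=reduced, readiness=readiness, selection=selection,
        model=model, confidence=confidence, assignments=assignments,
        evaluation=evaluation, retained_stages=retained,
        out_dir=Path(out_dir) if out_dir is not None else None,
        warnings_=merge_warnings + evaluation.warnings_,
    )
    if out_dir is not None:
        _write_artifacts(result, log, timings, make_plots, seed)
        _log(log, "done",
             f"total {time.perf_counter() - t0:.1f}s; artifacts in {out_dir}",
             echo)
    return result


def _write_artifacts(
    result: PipelineResult, log: list[str], timings: dict[str, float],
    make_plots: bool, seed: int,
) -> None:
    out = result.out_dir
    out.mkdir(parents=True, exist_ok=True)

    export_annotations(out, result.cohort, result.assignments,
                       result.confidence, result.model)
    if result.selection.table is not None:
        tab = result.selection.table.to_frame()
        tab["selected"] = tab["feature"].isin(result.selection.selected)
        tab["scenario"] = result.selection.scenario
        tab.to_csv(out / "stability_table.csv", index=False)
    result.evaluation.report.round(6).to_csv(out / "classification_report.csv")
    pd.DataFrame(
        result.evaluation.confusion_normalized.round(6),
        index=result.evaluation.class_order,
        columns=result.evaluation.class_order,
    ).to_csv(out / "confusion_matrix.csv")
    if result.evaluation.chi2 is not None:
        result.evaluation.chi2.round(6).to_csv(out / "chi2_results.csv",
                                               index=False)
    result.readiness.to_frame().to_csv(out / "readiness_report.csv",
                                       index=False)
    if make_plots:
        plot_stage_distribution(out, result.assignments,
                                result.retained_stages,
                                result.cohort.ordered_outcomes())
        plot_heatmap(out, result.cohort, result.assignments)
        plot_positional_confidence(out, result.confidence, result.model)

    with open(out / "run_log.txt", "w") as fh:
        fh.write(f"ebmkit {__version__} (python {platform.python_version()})\n")
        fh.write(f"seed: {seed}\n")
        for stage, secs in timings.items():
            fh.write(f"timing {stage}: {secs:.2f}s\n")
        fh.write("\n".join(log) + "\n")
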