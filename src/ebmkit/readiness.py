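"""Data readiness: validated ingestion of biomarker matrices and metadata.

Event-based models require a complete, finite, outlier-capped numeric matrix
aligned row-for-row with subject metadata.  This module performs every step
between "two files on disk" and that matrix: format and schema validation,
numeric coercion, missingness filtering, kNN imputation, upper-tail outlier
capping, and exact-ID alignment.  Each step reports what it did so malformed
inputs fail loudly with actionable messages instead of corrupting the model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.impute import KNNImputer

__all__ = [
    "ReadinessError",
    "FormatError",
    "SchemaError",
    "CoercionError",
    "Cohort",
    "CappingRule",
    "ReadinessReport",
    "load_tables",
    "validate_schema",
    "enforce_numeric",
    "filter_and_impute",
    "cap_outliers",
    "align",
    "prepare_cohort",
]

#: Tokens (case-insensitive) treated as missing values during numeric coercion.
NA_TOKENS = {"", "na", "nan", "null"}

#: Features with a missing fraction strictly above this are dropped.
MISSING_DROP_THRESHOLD = 0.20

_DELIMITERS = {".csv": ",", ".tsv": "\t", ".psv": "|"}


class ReadinessError(ValueError):
    """Base class for all data-readiness failures."""


class FormatError(ReadinessError):
    """Unsupported file format or unparseable file."""


class SchemaError(ReadinessError):
    """Metadata violates the required schema."""


class CoercionError(ReadinessError):
    """Non-numeric, non-missing tokens found in the data matrix."""

    def __init__(self, offenders: list[tuple[int, str, str]]):
        self.offenders = offenders
        preview = ", ".join(
            f"(row {r}, column {c!r}: {tok!r})" for r, c, tok in offenders[:5]
        )
        more = "" if len(offenders) <= 5 else f" and {len(offenders) - 5} more"
        super().__init__(
            f"non-numeric values in data matrix: {preview}{more}. "
            "All data cells must be numeric or one of the missing tokens "
            f"{sorted(NA_TOKENS)}."
        )


@dataclass
class CappingRule:
    """Per-feature upper-capping rule: values above ``q3 + 1.5*iqr`` are capped."""

    q3: pd.Series
    iqr: pd.Series

    @property
    def cap(self) -> pd.Series:
        return self.q3 + 1.5 * self.iqr


@dataclass
class ReadinessReport:
    """Structured account of everything readiness changed or rejected."""

    dropped_features_missingness: list[tuple[str, float]] = field(default_factory=list)
    imputed_features: list[str] = field(default_factory=list)
    capped_cells: int = 0
    schema_errors: list[str] = field(default_factory=list)
    coercion_errors: list[tuple[int, str, str]] = field(default_factory=list)
    dropped_subjects: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        rows = [("dropped_feature", f, f"missing_fraction={m:.4f}")
                for f, m in self.dropped_features_missingness]
        rows += [("imputed_feature", f, "") for f in self.imputed_features]
        rows += [("dropped_subject", s, "") for s in self.dropped_subjects]
        rows.append(("capped_cells", str(self.capped_cells), ""))
        return pd.DataFrame(rows, columns=["event", "item", "detail"])


@dataclass
class Cohort:
    """Aligned, complete, capped biomarker matrix plus subject metadata.

    Parameters
    ----------
    X : DataFrame, shape (n_subjects, n_features)
        Finite numeric values; index holds subject IDs.
    meta : DataFrame
        One row per subject, aligned with ``X``; contains at least
        ``SubjectID`` and ``Outcome``.
    outcome_order : list of str, optional
        Explicit ordinal arrangement of outcome labels (earliest first).
        Required for ordinal metrics with three or more classes and used to
        pick the baseline class for event distributions.
    """

    X: pd.DataFrame
    meta: pd.DataFrame
    outcome_order: list[str] | None = None

    @property
    def n_subjects(self) -> int:
        return len(self.X)

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    @property
    def feature_names(self) -> list[str]:
        return list(self.X.columns)

    @property
    def subject_ids(self) -> list[str]:
        return list(self.meta["SubjectID"].astype(str))

    @property
    def outcomes(self) -> pd.Series:
        return self.meta["Outcome"]

    def ordered_outcomes(self) -> list[str]:
        """Outcome labels in ordinal order (explicit order, else appearance order)."""
        if self.outcome_order is not None:
            return list(self.outcome_order)
        return list(pd.unique(self.outcomes))

    def restrict_features(self, features: list[str]) -> "Cohort":
        return Cohort(self.X[list(features)].copy(), self.meta.copy(),
                      self.outcome_order)


def load_tables(
    data_path: str | Path, meta_path: str | Path,
    delimiter: str | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read the data and metadata tables, inferring the delimiter from the extension.

    Only ``.csv``, ``.tsv`` and ``.psv`` (comma / tab / pipe) are accepted;
    the delimiter is taken from the extension alone, with no sniffing, unless
    an explicit ``delimiter`` overrides it.
    """
    tables = []
    for path in (data_path, meta_path):
        path = Path(path)
        suffix = path.suffix.lower()
        if suffix not in _DELIMITERS:
            raise FormatError(
                f"unsupported file format {path.suffix!r} for {path.name}: "
                "allowed extensions are .csv, .tsv, .psv"
            )
        if not path.exists():
            raise FormatError(f"file not found: {path}")
        try:
            table = pd.read_csv(path, sep=delimiter or _DELIMITERS[suffix],
                                dtype=str, keep_default_na=False)
        except Exception as exc:  # pragma: no cover - parser-specific
            raise FormatError(f"could not parse {path.name}: {exc}") from exc
        tables.append(table)
    return tables[0], tables[1]


def validate_schema(meta: pd.DataFrame) -> pd.DataFrame:
    """Check that metadata carries unique SubjectID and an Outcome column."""
    errors = []
    for col in ("SubjectID", "Outcome"):
        if col not in meta.columns:
            errors.append(f"metadata is missing required column {col!r}")
    if errors:
        raise SchemaError("; ".join(errors))
    ids = meta["SubjectID"].astype(str)
    dup = sorted(ids[ids.duplicated()].unique())
    if dup:
        raise SchemaError(f"duplicate SubjectID values in metadata: {dup}")
    out = meta.copy()
    out["SubjectID"] = ids
    return out


def enforce_numeric(data: pd.DataFrame) -> pd.DataFrame:
    """Coerce the data matrix to floats; NA tokens become NaN, anything else errors.

    The first column is treated as the subject identifier and left as strings.
    """
    if data.shape[1] < 2:
        raise SchemaError("data table must have an ID column plus at least one feature")
    id_col = data.columns[0]
    values = data.drop(columns=[id_col])
    cleaned = values.apply(lambda s: s.str.strip() if s.dtype == object else s)
    is_na = cleaned.apply(
        lambda s: s.str.lower().isin(NA_TOKENS) if s.dtype == object else s.isna()
    )
    numeric = cleaned.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & ~is_na
    if bad.any().any():
        rows, cols = np.where(bad.to_numpy())
        offenders = [
            (int(r), str(values.columns[c]), str(cleaned.iat[r, c]))
            for r, c in zip(rows, cols, strict=True)
        ]
        raise CoercionError(offenders)
    numeric = numeric.mask(is_na)
    numeric.insert(0, id_col, data[id_col].astype(str))
    return numeric


def filter_and_impute(
    X: pd.DataFrame, k: int = 5, report: ReadinessReport | None = None
) -> pd.DataFrame:
    """Drop features with >20% missing values; kNN-impute the rest (k=5).

    Imputation uses Euclidean distance over mutually observed features and
    the unweighted mean of the k nearest neighbours; it touches only cells
    that were originally missing.
    """
    if k < 1:
        raise ReadinessError(f"kNN imputation requires k >= 1, got {k}")
    report = report if report is not None else ReadinessReport()
    missing_frac = X.isna().mean(axis=0)
    drop = missing_frac[missing_frac > MISSING_DROP_THRESHOLD]
    report.dropped_features_missingness.extend(
        (str(f), float(m)) for f, m in drop.items()
    )
    kept = X.drop(columns=list(drop.index))
    if kept.shape[1] == 0:
        raise ReadinessError(
            "all features exceeded the 20% missingness threshold; nothing to model"
        )
    has_missing = kept.columns[kept.isna().any(axis=0)]
    report.imputed_features.extend(str(f) for f in has_missing)
    if len(has_missing) == 0:
        return kept
    imputer = KNNImputer(n_neighbors=k, weights="uniform")
    imputed = pd.DataFrame(
        imputer.fit_transform(kept), index=kept.index, columns=kept.columns
    )
    # only originally-missing cells may change
    observed = ~kept.isna()
    imputed = kept.where(observed, imputed)
    return imputed


def cap_outliers(
    X: pd.DataFrame, report: ReadinessReport | None = None
) -> tuple[pd.DataFrame, CappingRule]:
    """Cap values above Q3 + 1.5*IQR at that bound, per feature.

    Quartiles use linear interpolation between order statistics.  Capping is
    one-sided: low values are never raised.
    """
    q1 = X.quantile(0.25, interpolation="linear")
    q3 = X.quantile(0.75, interpolation="linear")
    rule = CappingRule(q3=q3, iqr=q3 - q1)
    cap = rule.cap
    n_capped = int((X.gt(cap, axis=1)).sum().sum())
    if report is not None:
        report.capped_cells += n_capped
    return X.clip(upper=cap, axis=1), rule


def align(
    data: pd.DataFrame,
    meta: pd.DataFrame,
    outcome_order: list[str] | None = None,
    report: ReadinessReport | None = None,
) -> Cohort:
    """Align the data matrix with metadata via exact SubjectID matching.

    Subjects present in only one table are dropped with a warning; the
    surviving subject order follows the metadata.
    """
    id_col = data.columns[0]
    data_ids = data[id_col].astype(str)
    if data_ids.duplicated().any():
        dup = sorted(data_ids[data_ids.duplicated()].unique())
        raise SchemaError(f"duplicate subject IDs in data table: {dup}")
    meta_ids = meta["SubjectID"].astype(str)
    common = set(data_ids) & set(meta_ids)
    if not common:
        raise ReadinessError(
            "no overlapping SubjectIDs between data and metadata; "
            "check that the ID columns refer to the same subjects"
        )
    lost = sorted((set(data_ids) | set(meta_ids)) - common)
    if lost:
        warnings.warn(
            f"{len(lost)} subject(s) present in only one table were dropped: {lost}",
            stacklevel=2,
        )
        if report is not None:
            report.dropped_subjects.extend(lost)
    meta_kept = meta[meta_ids.isin(common)].reset_index(drop=True)
    X = (
        data.set_index(data[id_col].astype(str))
        .drop(columns=[id_col])
        .loc[meta_kept["SubjectID"].astype(str)]
    )
    X.index.name = "SubjectID"
    return Cohort(X=X.astype(float), meta=meta_kept, outcome_order=outcome_order)


def prepare_cohort(
    data_path: str | Path,
    meta_path: str | Path,
    k: int = 5,
    outcome_order: list[str] | None = None,
    delimiter: str | None = None,
) -> tuple[Cohort, ReadinessReport]:
    """Full readiness pass: load, validate, coerce, filter/impute, cap, align."""
    report = ReadinessReport()
    data, meta = load_tables(data_path, meta_path, delimiter=delimiter)
    meta = validate_schema(meta)
    data = enforce_numeric(data)
    id_col = data.columns[0]
    ids = data[id_col]
    X = filter_and_impute(data.drop(columns=[id_col]), k=k, report=report)
    X, _ = cap_outliers(X, report=report)
    X.insert(0, id_col, ids)
    return align(X, meta, outcome_order=outcome_order, report=report), report
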