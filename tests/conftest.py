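import numpy as np
import pandas as pd
import pytest

from ebmkit.readiness import Cohort
from ebmkit.synthetic import GeneratorSpec, generate


def make_cohort(spec: GeneratorSpec, outcome_order=None):
    """Build an in-memory Cohort (plus ground truth) from a generator spec."""
    data, meta, truth = generate(spec)
    if outcome_order is None:
        outcome_order = spec.outcome_labels
    cohort = Cohort(
        X=data.set_index("SubjectID"), meta=meta, outcome_order=outcome_order
    )
    return cohort, truth


@pytest.fixture
def small_ordered_cohort():
    """120 subjects x 40 features, one subtype, strong planted staging."""
    spec = GeneratorSpec(
        n_subjects=120, n_features=40, n_informative=20, n_subtypes=1,
        n_stages=4, outcome_scheme="ordered_three_class", seed=1,
    )
    return make_cohort(spec)


@pytest.fixture
def csv_pair(tmp_path):
    """Write a small well-formed data/meta CSV pair; return their paths."""
    rng = np.random.default_rng(0)
    ids = [f"S{i}" for i in range(12)]
    data = pd.DataFrame(rng.normal(size=(12, 4)), columns=list("ABCD"))
    data.insert(0, "SubjectID", ids)
    meta = pd.DataFrame({
        "SubjectID": ids,
        "Outcome": ["case" if i % 2 else "control" for i in range(12)],
    })
    dpath, mpath = tmp_path / "data.csv", tmp_path / "meta.csv"
    data.to_csv(dpath, index=False)
    meta.to_csv(mpath, index=False)
    return dpath, mpath
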