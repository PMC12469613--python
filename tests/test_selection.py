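"""Ensemble stability selection: K rule, scores, scenarios, power, determinism."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ebmkit.selection import (SelectionConfig, StabilityTable, determine_k,
                              maybe_skip_selection, select_features,
                              stability_scores, train_fold_rankings)
from ebmkit.synthetic import GeneratorSpec

from conftest import make_cohort


@pytest.fixture(scope="module")
def selection_cohort():
    """150 subjects x 120 features (20 informative), single event stage so
    every planted feature separates the two outcome classes."""
    spec = GeneratorSpec(
        n_subjects=150, n_features=120, n_informative=20, n_subtypes=1,
        n_stages=1, outcome_scheme="binary_case_control",
        outcome_props=(0.4, 0.6), seed=2,
    )
    return make_cohort(spec)


class TestDetermineK:
    @pytest.mark.parametrize("p,u_max,expected", [
        (60, 50, 60),        # 3*u_max exceeds p -> capped at p
        (5000, 50, 250),     # ceil(0.05*5000)=250 dominates 3*50
        (1, 1, 1),
        (200, 150, 200),     # 3*150=450 capped at p
        (10000, 100, 500),
    ])
    def test_combiner_rule(self, p, u_max, expected):
        assert determine_k(p, u_max) == expected

    @given(p=st.integers(1, 20000), u_max=st.integers(1, 150))
    @settings(max_examples=200, deadline=None)
    def test_k_never_exceeds_p_and_floors_hold(self, p, u_max):
        k = determine_k(p, u_max)
        assert 1 <= k <= p
        assert k >= min(p, math.ceil(0.05 * p))

    def test_invalid_u_max(self):
        with pytest.raises(ValueError):
            determine_k(100, 151)


class TestStabilityScores:
    def _rankings(self, p, top_feature=0):
        # 15 identical importance vectors favoring `top_feature`
        imp = np.arange(p, dtype=float)
        imp[top_feature] = p + 1
        return {(c, f): imp.copy() for c in "abc" for f in range(5)}

    def test_always_top_scores_one(self):
        table = stability_scores(self._rankings(10), 3, [f"f{i}" for i in range(10)])
        assert table.stability[0] == 1.0

    def test_partial_appearances(self):
        rankings = self._rankings(10)
        # feature 0 demoted in 6 of the 15 lists -> 9/15 = 0.6
        for key in list(rankings)[:6]:
            rankings[key][0] = -1.0
        table = stability_scores(rankings, 3, [f"f{i}" for i in range(10)])
        assert table.appearances[0] == 9
        assert table.stability[0] == pytest.approx(0.6)

    def test_appearance_mass_conserved(self):
        k = 4
        table = stability_scores(self._rankings(12), k, [f"f{i}" for i in range(12)])
        assert table.appearances.sum() == 15 * k

    def test_boundary_tie_broken_by_name(self):
        imp = np.zeros(5)  # all tied: names decide the top-K
        rankings = {(c, f): imp.copy() for c in "abc" for f in range(5)}
        table = stability_scores(rankings, 2, ["b", "a", "e", "c", "d"])
        by_name = dict(zip(table.features, table.appearances))
        assert by_name["a"] == 15 and by_name["b"] == 15
        assert by_name["c"] == by_name["d"] == by_name["e"] == 0

    def test_k_exceeding_p_rejected(self):
        with pytest.raises(ValueError):
            stability_scores(self._rankings(5), 6, [f"f{i}" for i in range(5)])


def _table(stabilities):
    p = len(stabilities)
    return StabilityTable(
        features=[f"f{i:03d}" for i in range(p)],
        appearances=np.round(np.asarray(stabilities) * 15).astype(int),
        mean_rank=np.arange(p, dtype=float),
        k=p,
    )


class TestSelectFeatures:
    def test_abundant_takes_top_n(self):
        table = _table([1.0] * 80 + [0.0] * 20)
        res = select_features(table, n_final=66, m_min=10)
        assert res.scenario == "abundant"
        assert len(res.selected) == 66

    def test_clipped_extends_to_m_min(self):
        # 4 stable features, m_min 12 -> 4 + 8 clipped
        table = _table([0.8] * 4 + [0.2] * 26)
        res = select_features(table, n_final=20, m_min=12)
        assert res.scenario == "clipped"
        assert len(res.selected) == 12
        assert set(res.selected[:4]) == {f"f{i:03d}" for i in range(4)}

    def test_clipped_never_exceeds_n_final(self):
        table = _table([0.8] * 10 + [0.2] * 20)
        res = select_features(table, n_final=8, m_min=5)
        assert len(res.selected) == 8

    def test_fallback_takes_top_m_min(self):
        table = _table([0.4, 0.3, 0.2] + [0.1] * 27)
        res = select_features(table, n_final=20, m_min=10)
        assert res.scenario == "fallback"
        assert len(res.selected) == 10
        assert res.selected[0] == "f000"

    def test_exact_half_stability_is_not_stable(self):
        # 7/15 and 8/15 straddle the strict 0.5 threshold
        table = _table([8 / 15] * 3 + [7 / 15] * 27)
        res = select_features(table, n_final=20, m_min=3)
        assert res.scenario == "clipped"
        assert len(res.selected) == 3

    def test_m_min_larger_than_p_fatal(self):
        with pytest.raises(ValueError, match="reduce stages"):
            select_features(_table([0.5] * 5), n_final=5, m_min=6)

    def test_threshold_monotonicity_in_abundant_counts(self):
        table = _table(np.linspace(0, 1, 40))
        n_low = (table.stability > 0.4).sum()
        n_high = (table.stability > 0.6).sum()
        assert n_high <= n_low


class TestTrainAndSelect:
    def test_rankings_shape_and_determinism(self, selection_cohort):
        cohort, _ = selection_cohort
        cfg = SelectionConfig(u_max=30, base_seed=42)
        r1 = train_fold_rankings(cohort, cfg)
        r2 = train_fold_rankings(cohort, cfg)
        assert len(r1) == 15
        for key in r1:
            assert r1[key].shape == (120,)
            np.testing.assert_array_equal(r1[key], r2[key])

    def test_single_class_rejected(self, selection_cohort):
        cohort, _ = selection_cohort
        mono = cohort.restrict_features(cohort.feature_names)
        mono.meta = mono.meta.copy()
        mono.meta["Outcome"] = "same"
        with pytest.raises(ValueError, match="two outcome classes"):
            train_fold_rankings(mono, SelectionConfig())

    def test_planted_features_recovered(self, selection_cohort):
        """Power: strongly informative features reach S > 0.5 and are selected."""
        cohort, truth = selection_cohort
        res = maybe_skip_selection(cohort, SelectionConfig(u_max=30, base_seed=42),
                                   m_min=10)
        informative = {f for f, flag in zip(cohort.feature_names, truth.informative)
                       if flag}
        recall = len(informative & set(res.selected)) / len(informative)
        assert recall >= 0.9
        assert len(res.selected) <= 30

    def test_skip_below_activation_threshold(self):
        spec = GeneratorSpec(n_subjects=60, n_features=71, n_informative=40,
                             n_stages=4, seed=3,
                             outcome_scheme="three_class_with_control")
        cohort, _ = make_cohort(spec)
        res = maybe_skip_selection(cohort, SelectionConfig())
        assert res.scenario == "skipped"
        assert len(res.selected) == 71
        assert res.mean_stability == 1.0
        assert (res.table.stability == 1.0).all()

    def test_null_signal_gives_no_stable_features(self):
        """Negative control: with zero effect size nothing should look stable."""
        spec = GeneratorSpec(
            n_subjects=150, n_features=120, n_informative=20, n_stages=1,
            effect_size=0.0, outcome_scheme="binary_case_control", seed=4,
        )
        cohort, truth = make_cohort(spec)
        res = maybe_skip_selection(cohort, SelectionConfig(u_max=30, base_seed=42),
                                   m_min=10)
        stab = res.table.stability
        info_mean = stab[truth.informative].mean()
        noise_mean = stab[~truth.informative].mean()
        assert abs(info_mean - noise_mean) < 0.15
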