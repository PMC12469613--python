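"""Progression model: event densities, stage likelihoods, EM, MCMC, assignment."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.special import logsumexp
from scipy.stats import norm

from ebmkit.ebm import (EBMConfig, EventDistributions, assign_subjects,
                        e_step, fit_event_distributions, run_em, run_mcmc,
                        stage_logliks, subject_stage_loglik)
from ebmkit.ebm import _stage_indicator
from ebmkit.readiness import Cohort
from ebmkit.synthetic import GeneratorSpec

from conftest import make_cohort


def _toy_dists(M, shift=3.0):
    return EventDistributions(
        mu_pre=np.zeros(M), sd_pre=np.ones(M),
        mu_post=np.full(M, shift), sd_post=np.ones(M),
    )


class TestEventDistributions:
    def test_recovers_planted_moments(self):
        rng = np.random.default_rng(0)
        n = 200
        X = np.concatenate([rng.normal(0, 1, size=(n, 1)),
                            rng.normal(3, 1, size=(n, 1))])
        meta = pd.DataFrame({
            "SubjectID": [f"S{i}" for i in range(2 * n)],
            "Outcome": ["ctl"] * n + ["adv"] * n,
        })
        cohort = Cohort(pd.DataFrame(X, columns=["f"],
                                     index=meta["SubjectID"]), meta,
                        outcome_order=["ctl", "adv"])
        d = fit_event_distributions(cohort)
        # mixture-based estimates at 3-sigma separation: modest attenuation
        assert abs(d.mu_pre[0] - 0.0) < 0.3
        assert abs(d.mu_post[0] - 3.0) < 0.35

    def test_constant_biomarker_sigma_floored(self):
        meta = pd.DataFrame({"SubjectID": [f"S{i}" for i in range(10)],
                             "Outcome": ["a"] * 5 + ["b"] * 5})
        X = pd.DataFrame({"f": [2.0] * 10}, index=meta["SubjectID"])
        d = fit_event_distributions(Cohort(X, meta, ["a", "b"]))
        assert d.sd_pre[0] > 0 and d.sd_post[0] > 0

    def test_no_baseline_uses_mixture_path(self):
        rng = np.random.default_rng(1)
        X = np.concatenate([rng.normal(0, 1, 150), rng.normal(5, 1, 150)])
        rng.shuffle(X)
        meta = pd.DataFrame({"SubjectID": [f"S{i}" for i in range(300)],
                             "Outcome": ["stageA"] * 150 + ["stageB"] * 150})
        cohort = Cohort(pd.DataFrame({"f": X}, index=meta["SubjectID"]), meta)
        d = fit_event_distributions(cohort, baseline_class=None)
        assert d.mixture_fallback
        assert d.mu_pre[0] < d.mu_post[0]
        assert abs(d.mu_pre[0]) < 0.5 and abs(d.mu_post[0] - 5) < 0.5

    def test_tiny_anchor_class_warns(self):
        rng = np.random.default_rng(2)
        meta = pd.DataFrame({"SubjectID": [f"S{i}" for i in range(50)],
                             "Outcome": ["ctl"] * 2 + ["adv"] * 48})
        X = pd.DataFrame({"f": rng.normal(size=50)}, index=meta["SubjectID"])
        with pytest.warns(UserWarning, match="fewer than 3"):
            fit_event_distributions(Cohort(X, meta, ["ctl", "adv"]))


class TestStageLoglik:
    def test_boundary_stages_and_hand_computed_interior(self):
        d = _toy_dists(2)
        clusters = np.array([0, 1])     # one biomarker per stage, S=2
        x = np.array([1.0, -0.5])
        # stage 0: both pre; stage 2: both post; stage 1: first post
        expected = {
            0: norm.logpdf(1.0) + norm.logpdf(-0.5),
            1: norm.logpdf(1.0, 3) + norm.logpdf(-0.5),
            2: norm.logpdf(1.0, 3) + norm.logpdf(-0.5, 3),
        }
        for s, value in expected.items():
            assert subject_stage_loglik(x, clusters, s, d) == pytest.approx(value)

    def test_vectorized_matches_scalar(self):
        rng = np.random.default_rng(3)
        d = _toy_dists(5)
        X = rng.normal(size=(7, 5))
        clusters = np.array([0, 0, 1, 2, 2])
        lp, lq = d.log_densities(X)
        L = stage_logliks(lp, lq, clusters, 3)
        for n in range(7):
            for s in range(4):
                assert L[n, s] == pytest.approx(
                    subject_stage_loglik(X[n], clusters, s, d))


class TestEStep:
    def test_posterior_normalized_and_finite(self):
        rng = np.random.default_rng(4)
        d = _toy_dists(6)
        X = rng.normal(size=(20, 6)) * 50       # extreme values: underflow risk
        lp, lq = d.log_densities(X)
        clusters = np.array([[0, 0, 1, 1, 2, 2]])
        r, ll = e_step(lp, lq, clusters, np.array([1.0]), 3)
        assert np.isfinite(ll)
        np.testing.assert_allclose(r.sum(axis=(1, 2)), 1.0, atol=1e-9)

    def test_baseline_subject_maps_to_stage_zero(self):
        d = _toy_dists(4, shift=6.0)
        x = np.zeros((1, 4))                    # exactly at pre-event means
        lp, lq = d.log_densities(x)
        clusters = np.array([[0, 0, 1, 1]])
        r, _ = e_step(lp, lq, clusters, np.array([1.0]), 2)
        assert r[0, 0].argmax() == 0

    def test_zero_mixture_weight_kills_subtype(self):
        rng = np.random.default_rng(5)
        d = _toy_dists(4)
        lp, lq = d.log_densities(rng.normal(size=(10, 4)))
        clusters = np.array([[0, 0, 1, 1], [1, 1, 0, 0]])
        r, _ = e_step(lp, lq, clusters, np.array([1.0, 0.0]), 2)
        assert r[:, 1, :].sum() == 0.0


class TestRunEM:
    def test_loglik_trace_improves_and_deterministic(self, small_ordered_cohort):
        cohort, _ = small_ordered_cohort
        cfg = EBMConfig(n_subtypes=1, n_stages=4, min_cluster=5, em_iters=20,
                        seed=3)
        m1 = run_em(cohort, cfg)
        m2 = run_em(cohort, cfg)
        assert m1.loglik_trace[-1] >= m1.loglik_trace[0] - 1e-6
        assert m1.loglik_trace == m2.loglik_trace
        np.testing.assert_array_equal(m1.clusters, m2.clusters)

    def test_partition_is_valid(self, small_ordered_cohort):
        cohort, _ = small_ordered_cohort
        cfg = EBMConfig(n_subtypes=1, n_stages=4, min_cluster=5, em_iters=20,
                        seed=3)
        model = run_em(cohort, cfg)
        counts = np.bincount(model.clusters[0], minlength=4)
        assert counts.sum() == cohort.n_features
        assert counts.min() >= 5
        assert model.pi.sum() == pytest.approx(1.0)

    def test_single_subtype_recovers_planted_partition(self):
        spec = GeneratorSpec(n_subjects=200, n_features=40, n_informative=40,
                             n_subtypes=1, n_stages=4, noise_sd=1.0,
                             effect_size=10.0, seed=6,
                             outcome_scheme="ordered_three_class")
        cohort, truth = make_cohort(spec)
        cfg = EBMConfig(n_subtypes=1, n_stages=4, min_cluster=5, em_iters=30,
                        seed=42)
        model = run_em(cohort, cfg)
        agreement = (model.clusters[0] == truth.clusters[0]).mean()
        assert agreement >= 0.9

    def test_too_few_biomarkers_rejected(self, small_ordered_cohort):
        cohort, _ = small_ordered_cohort
        cfg = EBMConfig(n_subtypes=1, n_stages=4, min_cluster=11, em_iters=5)
        with pytest.raises(ValueError, match="min_cluster"):
            run_em(cohort, cfg)


@pytest.fixture(scope="module")
def fitted():
    spec = GeneratorSpec(n_subjects=150, n_features=24, n_informative=24,
                         n_subtypes=1, n_stages=3, effect_size=5.0, seed=8,
                         outcome_scheme="ordered_three_class")
    cohort, truth = make_cohort(spec)
    cfg = EBMConfig(n_subtypes=1, n_stages=3, min_cluster=5, em_iters=20,
                    mcmc_burnin=300, mcmc_final=1200, seed=42)
    model = run_em(cohort, cfg)
    return cohort, truth, cfg, model, run_mcmc(cohort, model, cfg)


class TestMCMC:
    def test_rows_sum_to_one(self, fitted):
        *_, conf = fitted
        np.testing.assert_allclose(conf.P[0].sum(axis=1), 1.0, atol=1e-9)

    def test_modal_stage_matches_em_on_separated_data(self, fitted):
        _, _, _, model, conf = fitted
        modal = conf.P[0].argmax(axis=1)
        assert (modal == model.clusters[0]).mean() >= 0.9

    def test_best_sampled_loglik_not_below_em(self, fitted):
        cohort, _, cfg, model, conf = fitted
        lp, lq = model.dists.log_densities(cohort.X.to_numpy())
        L = stage_logliks(lp, lq, model.clusters[0], 3)
        em_ll = logsumexp(L - np.log(4), axis=1).sum()
        assert conf.best_loglik >= em_ll - 1e-6

    def test_pure_noise_gives_high_entropy_rows(self):
        """With zero planted effect the sampler should not concentrate."""
        spec = GeneratorSpec(n_subjects=100, n_features=12, n_informative=12,
                             n_subtypes=1, n_stages=3, effect_size=0.0, seed=9,
                             outcome_scheme="ordered_three_class")
        cohort, _ = make_cohort(spec)
        cfg = EBMConfig(n_subtypes=1, n_stages=3, min_cluster=2, em_iters=10,
                        mcmc_burnin=500, mcmc_final=5000, seed=42)
        model = run_em(cohort, cfg, dists=_toy_dists(12, shift=0.5))
        conf = run_mcmc(cohort, model, cfg)
        # mean row entropy within 40% of the uniform maximum
        P = np.clip(conf.P[0], 1e-12, 1)
        entropy = -(P * np.log(P)).sum(axis=1).mean()
        assert entropy > 0.6 * np.log(3)


class TestAssignSubjects:
    def _model_with_posterior(self, r):
        cfg = EBMConfig(n_subtypes=r.shape[1], n_stages=r.shape[2] - 1,
                        min_cluster=1)
        M = 4
        return type("M", (), {
            "posterior": r,
            "config": cfg,
        })()

    def test_map_and_tie_breaks(self):
        r = np.zeros((3, 2, 4))
        r[0, 1, 2] = 1.0                       # clear winner
        r[1, 0, 1] = r[1, 0, 2] = 0.5          # stage tie -> lower stage
        r[2, 0, 3] = r[2, 1, 3] = 0.5          # subtype tie -> lower subtype
        out = assign_subjects(self._model_with_posterior(r))
        assert list(out["Subtype"]) == [2, 1, 1]
        assert list(out["Stage"]) == [2, 1, 3]

    def test_stage_zero_reported_as_one(self):
        r = np.zeros((1, 1, 3))
        r[0, 0, 0] = 1.0
        out = assign_subjects(self._model_with_posterior(r))
        assert out["Stage"].iloc[0] == 1
        assert out["InternalStage"].iloc[0] == 0


def test_brute_force_partition_oracle():
    """Exhaustive enumeration of size-constrained partitions matches the
    EM + MCMC optimum on well-separated data (M=6, S=3, K=1)."""
    spec = GeneratorSpec(n_subjects=150, n_features=6, n_informative=6,
                         n_subtypes=1, n_stages=3, effect_size=5.0, seed=5,
                         outcome_scheme="ordered_three_class")
    cohort, _ = make_cohort(spec)
    cfg = EBMConfig(n_subtypes=1, n_stages=3, min_cluster=2, em_iters=30,
                    mcmc_burnin=500, mcmc_final=2000, seed=42)
    dists = fit_event_distributions(cohort)
    lp, lq = dists.log_densities(cohort.X.to_numpy())
    D = lq - lp
    pre_tot = lp.sum(axis=1)

    def partition_loglik(z):
        L = pre_tot[:, None] + D @ _stage_indicator(np.asarray(z), 3)
        return logsumexp(L - np.log(4), axis=1).sum()

    best = max(
        partition_loglik(z)
        for z in itertools.product(range(3), repeat=6)
        if np.bincount(z, minlength=3).min() >= 2
    )
    model = run_em(cohort, cfg, dists=dists)
    conf = run_mcmc(cohort, model, cfg)
    assert conf.best_loglik == pytest.approx(best, abs=1e-6)
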