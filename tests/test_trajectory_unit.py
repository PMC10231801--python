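"""Trajectory model building blocks (cheap checks; recovery lives in the
acceptance suite)."""

import math

import numpy as np
import pytest

from xdp_progression import SimulationConfig, simulate_cohort
from xdp_progression.likelihoods import ContinuousParams, CountParams, OrdinalParams, continuous_loglik, count_loglik, ordinal_loglik
from xdp_progression.trajectory import (
    _cnt_ll,
    _cont_ll,
    _ord_ll,
    association_tests,
    fit_trajectory,
    predict_measure_trajectory,
    progression_summary,
)


class TestProgressionSummary:
    def test_zero_before_onset(self):
        assert progression_summary(onset=50.0, rate=2.0, age=45.0) == 0.0

    def test_linear_after_onset(self):
        assert progression_summary(onset=50.0, rate=1.7, age=52.0) == pytest.approx(3.4)

    def test_monotone_in_age(self):
        ages = np.linspace(30, 70, 50)
        scores = progression_summary(onset=48.0, rate=0.9, age=ages)
        assert np.all(np.diff(scores) >= 0)


class TestInternalLikelihoods:
    """The sampler's vectorized log-likelihoods agree with the public
    per-observation oracles (up to documented additive constants)."""

    def test_ordinal(self, rng):
        for _ in range(30):
            K = int(rng.integers(2, 8))
            thr = np.sort(rng.normal(0, 2, size=K - 1)) + 1e-4 * np.arange(K - 1)
            b1, b2 = rng.normal(0, 0.1), rng.normal(0, 0.5)
            params = OrdinalParams(tuple(thr), b1, b2)
            levels = np.arange(K, dtype=float)
            n = 7
            k = rng.integers(0, K, size=n)
            age = rng.normal(0, 8, size=n)
            rts = np.abs(rng.normal(size=n))  # rate * [age-onset]+ composite
            got = _ord_ll(thr, b1, b2, k, age, rts)
            want = sum(
                ordinal_loglik(params, levels, float(k[i]), age[i], 1.0, age[i] - rts[i])
                for i in range(n)
            )
            assert got == pytest.approx(want, abs=1e-10)

    def test_continuous_up_to_constants(self, rng):
        a, b1, b2, ls = 1.0, 0.02, 0.1, math.log(0.7)
        params = ContinuousParams(a, b1, b2, math.exp(ls))
        n = 9
        logy = rng.normal(1, 0.5, size=n)
        age = rng.normal(0, 5, size=n)
        rts = np.abs(rng.normal(size=n))
        got = _cont_ll(a, b1, b2, ls, logy, age, rts)
        want = sum(
            continuous_loglik(params, math.exp(logy[i]), age[i], 1.0, age[i] - rts[i])
            for i in range(n)
        )
        const = -n * 0.5 * math.log(2 * math.pi) - logy.sum()  # dropped by the sampler
        assert got == pytest.approx(want - const, abs=1e-10)

    def test_count_up_to_constants(self, rng):
        from scipy.special import gammaln

        a, b1, b2 = 1.5, 0.01, -0.2
        params = CountParams(a, b1, b2)
        n = 9
        y = rng.integers(0, 20, size=n).astype(float)
        off = rng.uniform(0.5, 5, size=n)
        age = rng.normal(0, 5, size=n)
        rts = np.abs(rng.normal(size=n))
        got = _cnt_ll(a, b1, b2, y, off, age, rts)
        want = sum(
            count_loglik(params, y[i], off[i], age[i], 1.0, age[i] - rts[i]) for i in range(n)
        )
        assert got == pytest.approx(want + gammaln(y + 1).sum(), abs=1e-10)


class TestPredictTrajectory:
    def test_gene_negative_dynamics_driven_by_age_alone(self, catalogue):
        spec = catalogue["swallow_duration"]
        params = ContinuousParams(alpha=1.5, beta_age=0.02, beta_rate=0.4, sigma=0.3)
        ages = np.linspace(20, 70, 11)
        traj = predict_measure_trajectory(spec, params, onset=45.0, rate=0.0, ages=ages)
        expected = np.exp(params.alpha + params.beta_age * (ages - 40.0))
        assert traj == pytest.approx(expected)

    def test_monotone_and_continuous_at_onset(self, catalogue):
        spec = catalogue["updrs3_10_gait"]
        params = OrdinalParams(thresholds=(0.5, 1.5, 2.5, 3.5), beta_age=0.0, beta_rate=-0.4)
        ages = np.linspace(30, 60, 121)
        traj = predict_measure_trajectory(spec, params, onset=45.0, rate=1.0, ages=ages)
        assert np.all(np.diff(traj) >= -1e-12)
        i = np.searchsorted(ages, 45.0)
        assert abs(traj[i] - traj[i - 1]) < 0.05  # no jump at onset

    def test_empty_age_grid_rejected(self, catalogue):
        with pytest.raises(ValueError, match="empty"):
            predict_measure_trajectory(
                catalogue["mpt"], ContinuousParams(1, 0, 0, 1), onset=40, rate=1, ages=[]
            )


class TestSmallFit:
    @pytest.fixture(scope="class")
    def tiny_fit(self):
        config = SimulationConfig(n_symptomatic=6, n_presymptomatic=1, n_negative=5, seed=77)
        cohort, truth = simulate_cohort(config)
        mids = ["updrs3_10_gait", "bfm_dis_speech", "mpt", "lip_strength"]
        fit = fit_trajectory(cohort, measure_ids=mids, n_chains=2, n_warmup=100, n_draws=150, seed=1)
        return cohort, truth, fit

    def test_summary_structure(self, tiny_fit):
        cohort, truth, fit = tiny_fit
        assert len(fit.subject_ids) == 6
        assert np.all(fit.onset_interval[:, 0] <= fit.onset_mean)
        assert np.all(fit.onset_mean <= fit.onset_interval[:, 1])
        assert np.all(fit.rate_mean > 0)
        assert set(fit.measure_summaries) == {"updrs3_10_gait", "bfm_dis_speech", "mpt", "lip_strength"}
        assert "sigma" in fit.measure_summaries["mpt"]
        assert fit.diagnostics["n_subject_latents"] == 6

    def test_fixed_onsets_are_respected(self, tiny_fit):
        cohort, truth, _ = tiny_fit
        fixed = {s: truth.onsets[s] for s in truth.onsets if s.startswith("P")}
        refit = fit_trajectory(
            cohort,
            measure_ids=["updrs3_10_gait", "mpt"],
            n_chains=1,
            n_warmup=50,
            n_draws=50,
            seed=2,
            fixed_onsets=fixed,
        )
        for sid in refit.subject_ids:
            assert refit.onset(sid) == pytest.approx(fixed[sid], abs=1e-9)

    def test_pinned_measure_params_unchanged(self, tiny_fit):
        cohort, truth, fit = tiny_fit
        pinned = {"mpt": fit.measure_summaries["mpt"]}
        refit = fit_trajectory(
            cohort,
            measure_ids=["mpt"],
            n_chains=1,
            n_warmup=30,
            n_draws=30,
            seed=3,
            fixed_onsets={s: fit.onset(s) for s in fit.subject_ids},
            fixed_measure_params=pinned,
        )
        for key in ("alpha", "beta_age", "beta_rate", "sigma"):
            assert refit.measure_summaries["mpt"][key] == pytest.approx(pinned["mpt"][key], abs=1e-12)

    def test_requires_symptomatic_subjects(self):
        cohort, _ = simulate_cohort(SimulationConfig(n_symptomatic=0, n_presymptomatic=2, n_negative=3, seed=6))
        with pytest.raises(ValueError, match="symptomatic"):
            fit_trajectory(cohort, measure_ids=["mpt"], n_chains=1, n_warmup=5, n_draws=5)


class TestAssociations:
    def test_report_keys_and_degenerate_grouping(self, tiny_fit_cohort=None):
        config = SimulationConfig(n_symptomatic=6, n_presymptomatic=0, n_negative=0, seed=31)
        cohort, truth = simulate_cohort(config)
        # collapse everyone into one family: family comparison must be skipped
        for s in cohort.subjects:
            s.family_id = "F001"
        fit = fit_trajectory(cohort, measure_ids=["updrs3_10_gait", "mpt"], n_chains=1, n_warmup=40, n_draws=60, seed=4)
        report = association_tests(fit, cohort)
        assert set(report) == {"onset_vs_repeat", "rate_vs_repeat", "rate_by_initial_symptom", "rate_by_family"}
        assert "skipped" in report["rate_by_family"]
        assert report["onset_vs_repeat"]["r"] < 0  # repeat-size slope propagates
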