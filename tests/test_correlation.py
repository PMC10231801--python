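"""Bayesian correlation model: orientation, recovery, validity, clustering."""

import numpy as np
import pandas as pd
import pytest

from xdp_progression.catalogue import MeasureSpec
from xdp_progression.correlation import (
    CorrelationEstimate,
    build_analysis_matrix,
    cluster_variables,
    estimate_correlation,
    orient_severity,
    rank_inverse_normal,
)


def _spec(direction):
    return MeasureSpec(
        measure_id="m", label="m", group="g", value_kind="positive_real", severity_direction=direction
    )


class TestOrientation:
    def test_negation_for_severity_decreasing(self):
        assert orient_severity([1.0, -2.0, 3.0], _spec(-1)) == pytest.approx([-1.0, 2.0, -3.0])

    def test_identity_for_severity_increasing(self):
        assert orient_severity([1.0, -2.0], _spec(1)) == pytest.approx([1.0, -2.0])

    def test_involution(self, rng):
        x = rng.normal(size=20)
        assert orient_severity(orient_severity(x, _spec(-1)), _spec(-1)) == pytest.approx(x)


def test_rank_inverse_normal_handles_missing_and_ties():
    x = np.array([3.0, 1.0, np.nan, 3.0, 10.0])
    z = rank_inverse_normal(x)
    assert np.isnan(z[2])
    assert z[1] < z[0] == z[3] < z[4]  # ties get equal scores
    assert abs(np.nanmean(z)) < 1e-6  # symmetric scores


def _mvn_missing_frame(R, n, missing, rng):
    p = R.shape[0]
    X = rng.multivariate_normal(np.zeros(p), R, size=n)
    mask = rng.random(X.shape) < missing
    X[mask] = np.nan
    return pd.DataFrame(X, columns=[f"v{i}" for i in range(p)])


class TestEstimate:
    def test_duplicated_variable_recovers_unit_correlation(self, rng):
        x = rng.normal(size=60)
        df = pd.DataFrame({"a": x, "b": x, "c": rng.normal(size=60)})
        est = estimate_correlation(df, n_draws=300, n_burn=100, seed=1)
        assert est.pair("a", "b")[0] >= 0.99

    def test_known_matrix_recovery_under_mcar(self, rng):
        p = 6
        R = 0.5 * np.eye(p) + 0.5
        df = _mvn_missing_frame(R, 200, 0.09, rng)
        est = estimate_correlation(df, n_draws=400, n_burn=150, seed=2, transform=False)
        err = np.abs(est.mean - R)
        assert err.max() < 0.2

    def test_independent_variables_yield_small_estimates(self, rng):
        df = pd.DataFrame(rng.normal(size=(200, 5)), columns=list("abcde"))
        est = estimate_correlation(df, n_draws=400, n_burn=150, seed=3, transform=False)
        off = est.mean[~np.eye(5, dtype=bool)]
        assert np.abs(off).max() < 0.25
        # intervals should cover zero for most null pairs
        covered = (np.abs(est.mean) < est.halfwidth)[~np.eye(5, dtype=bool)]
        assert covered.mean() > 0.8

    def test_output_always_valid_correlation_matrix(self, rng):
        R = np.eye(4)
        R[0, 1] = R[1, 0] = 0.9
        df = _mvn_missing_frame(R, 60, 0.35, rng)  # heavy missingness
        est = estimate_correlation(df, n_draws=200, n_burn=100, seed=4, transform=False)
        assert np.allclose(est.mean, est.mean.T)
        assert np.allclose(np.diag(est.mean), 1.0)
        assert np.linalg.eigvalsh(est.mean).min() > -1e-10
        assert np.all(np.abs(est.mean) <= 1 + 1e-12)

    def test_degenerate_variable_dropped_with_warning(self, rng):
        df = pd.DataFrame({"a": rng.normal(size=30), "b": np.ones(30), "c": rng.normal(size=30)})
        with pytest.warns(UserWarning, match="degenerate"):
            est = estimate_correlation(df, n_draws=100, n_burn=50, seed=5)
        assert est.variables == ["a", "c"]

    def test_too_few_variables_rejected(self, rng):
        with pytest.raises(ValueError):
            estimate_correlation(pd.DataFrame({"a": rng.normal(size=10)}), n_draws=10, n_burn=5)


class TestAnalysisMatrix:
    def test_shape_and_constant_replication(self, small_cohort):
        cohort, _ = small_cohort
        df = build_analysis_matrix(cohort)
        n_sym_visits = sum(len(s.visits) for s in cohort.subjects_in_group("positive_symptomatic"))
        assert df.shape == (n_sym_visits, 102)
        for sid, g in df.groupby(level="subject_id"):
            for var in ("repeat_size", "reported_onset", "height"):
                vals = g[var].dropna().unique()
                assert len(vals) <= 1  # subject-level constants replicated

    def test_requires_symptomatic_stratum(self):
        from xdp_progression import SimulationConfig, simulate_cohort

        cohort, _ = simulate_cohort(SimulationConfig(n_symptomatic=2, n_presymptomatic=0, n_negative=3, seed=2))
        with pytest.raises(ValueError, match="symptomatic"):
            build_analysis_matrix(cohort)


class TestClustering:
    def test_perfectly_correlated_pair_merges_first(self):
        R = np.eye(3)
        R[0, 1] = R[1, 0] = 1.0
        est = CorrelationEstimate(variables=["a", "b", "c"], mean=R, halfwidth=np.zeros((3, 3)))
        Z, order = cluster_variables(est)
        assert set(map(int, Z[0, :2])) == {0, 1}  # first merge joins the duplicates

    def test_block_structure_recovered(self, rng):
        blocks = [["a", "b", "c"], ["d", "e"], ["f", "g"]]
        p = 7
        R = np.eye(p) * 0.2
        names = [v for b in blocks for v in b]
        for b in blocks:
            idx = [names.index(v) for v in b]
            for i in idx:
                for j in idx:
                    R[i, j] = 0.8
        np.fill_diagonal(R, 1.0)
        X = rng.multivariate_normal(np.zeros(p), R, size=300)
        df = pd.DataFrame(X, columns=names)
        est = estimate_correlation(df, n_draws=200, n_burn=100, seed=6, transform=False)
        Z, order = cluster_variables(est)
        # each planted block appears contiguously in the leaf order
        for b in blocks:
            pos = sorted(order.index(v) for v in b)
            assert pos == list(range(pos[0], pos[0] + len(b)))

    def test_single_variable_trivial_tree(self):
        est = CorrelationEstimate(variables=["a"], mean=np.eye(1), halfwidth=np.zeros((1, 1)))
        Z, order = cluster_variables(est)
        assert Z.shape == (0, 4) and order == ["a"]
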