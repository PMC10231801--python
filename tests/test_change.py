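"""Signed-rank change testing: imputation rule, exact null, BH adjustment."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from xdp_progression import SimulationConfig, simulate_cohort
from xdp_progression.change import bh_adjust, first_last_pair, run_change_tests, wilcoxon_signed_rank


def enumeration_p(diffs):
    """Brute-force two-sided p over all 2^n sign assignments (oracle)."""
    from scipy.stats import rankdata

    d = np.asarray(diffs, float)
    d = d[d != 0]
    ranks = rankdata(np.abs(d))
    w_obs = float(np.sum(np.sign(d) * ranks))
    n = len(d)
    count = 0
    for signs in itertools.product([-1.0, 1.0], repeat=n):
        w = float(np.sum(np.asarray(signs) * ranks))
        if abs(w) >= abs(w_obs) - 1e-12:
            count += 1
    return count / 2**n


class TestFirstLastPair:
    def test_no_imputation_needed(self):
        assert first_last_pair([5, None, None, 7]) == (5, 7)

    def test_nocb_then_locf(self):
        assert first_last_pair([None, 3, 4, None]) == (3, 4)

    def test_single_observation_excluded(self):
        assert first_last_pair([None, 6, None, None]) is None

    def test_fully_missing_excluded(self):
        assert first_last_pair([None, None]) is None


class TestWilcoxon:
    def test_all_zero_differences_untestable(self):
        w, p, n = wilcoxon_signed_rank([0.0, 0.0, 0.0])
        assert math.isnan(w) and p is None and n == 0

    def test_example_all_positive(self):
        w, p, n = wilcoxon_signed_rank([1.0, 2.0, 3.0])
        assert w == 6 and n == 3
        assert p == pytest.approx(0.25, abs=1e-15)

    def test_example_mixed_signs_matches_enumeration(self):
        diffs = [2.0, -1.0, 3.0, 5.0]
        w, p, _ = wilcoxon_signed_rank(diffs)
        assert p == pytest.approx(enumeration_p(diffs), abs=1e-12)

    def test_exact_matches_enumeration_on_random_vectors(self, rng):
        """200 tie-free vectors with n <= 10: exact p equals the 2^n oracle."""
        for _ in range(200):
            n = int(rng.integers(1, 11))
            d = rng.normal(size=n)
            while np.unique(np.abs(d)).size < n or np.any(d == 0):
                d = rng.normal(size=n)
            _, p, _ = wilcoxon_signed_rank(d)
            assert p == pytest.approx(enumeration_p(d), abs=1e-12)

    @given(st.lists(st.floats(-50, 50).filter(lambda x: abs(x) > 1e-6), min_size=1, max_size=12))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_antisymmetry(self, diffs):
        w1, p1, n1 = wilcoxon_signed_rank(diffs)
        w2, p2, n2 = wilcoxon_signed_rank([-d for d in diffs])
        assert w1 == pytest.approx(-w2)
        assert n1 == n2
        assert p1 == pytest.approx(p2, abs=1e-12)

    def test_normal_approximation_with_ties(self):
        # ties force the tie-corrected normal path: Var(W) = sum(rank^2)
        d = np.array([1.0, 1.0, -1.0, 2.0, 2.0, 3.0])
        from scipy.stats import norm, rankdata

        ranks = rankdata(np.abs(d))
        w = float(np.sum(np.sign(d) * ranks))
        expected = 2 * norm.sf(abs(w) / math.sqrt(np.sum(ranks**2)))
        w_got, p_got, _ = wilcoxon_signed_rank(d)
        assert w_got == pytest.approx(w)
        assert p_got == pytest.approx(expected, rel=1e-12)

    def test_large_n_uses_normal_approximation(self, rng):
        d = rng.normal(0.3, 1.0, size=40)
        _, p, n = wilcoxon_signed_rank(d)
        assert n == 40 and 0 <= p <= 1


class TestBH:
    def test_single_p_identity(self):
        assert bh_adjust([0.03]) == pytest.approx([0.03])

    def test_two_values(self):
        assert bh_adjust([0.001, 0.5]) == pytest.approx([0.002, 0.5])

    def test_cumulative_min(self):
        assert bh_adjust([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])

    def test_matches_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests

        for _ in range(50):
            p = rng.uniform(size=int(rng.integers(1, 40)))
            ours = bh_adjust(p)
            _, theirs, _, _ = multipletests(p, method="fdr_bh")
            assert ours == pytest.approx(theirs, abs=1e-12)

    def test_rejection_sets_match_stepup_rule(self, rng):
        for level in (0.01, 0.05, 0.1):
            p = rng.uniform(size=30) ** 2
            adj = bh_adjust(p)
            # textbook step-up: reject all p(i) with i <= max{k: p(k) <= k/m q}
            order = np.argsort(p)
            m = len(p)
            ks = [k for k in range(1, m + 1) if p[order[k - 1]] <= k / m * level]
            rejected_textbook = set(order[: max(ks)] if ks else [])
            assert set(np.where(adj <= level)[0]) == rejected_textbook

    @given(st.permutations(list(range(6))))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_permutation_equivariance(self, perm):
        p = np.array([0.001, 0.01, 0.04, 0.2, 0.5, 0.9])
        adj = bh_adjust(p)
        assert bh_adjust(p[list(perm)]) == pytest.approx(adj[list(perm)])

    def test_nan_passthrough_does_not_count(self):
        adj = bh_adjust([0.01, np.nan, 0.5])
        assert math.isnan(adj[1])
        assert adj[0] == pytest.approx(0.02)  # m = 2, not 3

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([1.2])


class TestRunChangeTests:
    def test_requires_symptomatic_subjects(self):
        cohort, _ = simulate_cohort(SimulationConfig(n_symptomatic=0, n_presymptomatic=0, n_negative=5, seed=7))
        with pytest.raises(ValueError, match="symptomatic"):
            run_change_tests(cohort)

    def test_full_pipeline_output_shape(self, small_cohort):
        cohort, _ = small_cohort
        results = run_change_tests(cohort, fdr_level=0.05)
        assert len(results) == 99
        testable = [r for r in results if r.p_adjusted is not None]
        assert all(r.p_adjusted >= r.p_value - 1e-15 for r in testable)
        # sorted by adjusted p
        vals = [r.p_adjusted for r in testable]
        assert vals == sorted(vals)

    def test_strong_effects_enriched_among_flagged(self):
        """Measures given strong progression effects dominate the discoveries
        over a null background."""
        subset = ["tongue_strength", "mpt", "swallow_duration", "ddk_duration_ka", "lip_strength", "ddk_count_ka"]
        config = SimulationConfig(
            n_symptomatic=29,
            n_presymptomatic=0,
            n_negative=0,
            seed=42,
            effect_subset=subset,
            beta_rate_continuous=(0.2, 0.3),
            beta_rate_count=(0.8, 1.2),
            beta_rate_ddk=(0.15, 0.25),
            missing_fraction=0.0,
        )
        cohort, _ = simulate_cohort(config)
        results = run_change_tests(cohort)
        flagged = {r.test_unit for r in results if r.significant}
        assert len(flagged & set(subset)) >= 3  # most planted effects found
        # discoveries are dominated by the planted measures
        assert len(flagged & set(subset)) >= len(flagged) / 2
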