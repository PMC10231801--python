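"""Principal-variables PVE functional and greedy battery selection."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from xdp_progression.battery import (
    BatteryBlock,
    default_battery_blocks,
    pve,
    reference_battery,
    report_battery,
    select_battery,
)
from xdp_progression.catalogue import build_default_catalogue, correlation_variables
from xdp_progression.correlation import CorrelationEstimate


def random_correlation(p, rng):
    A = rng.normal(size=(p, p + 3))
    S = A @ A.T
    d = np.sqrt(np.diag(S))
    return S / np.outer(d, d)


def _estimate(R, names=None):
    names = names or [f"v{i}" for i in range(R.shape[0])]
    return CorrelationEstimate(variables=names, mean=R, halfwidth=np.zeros(R.shape))


class TestPVE:
    def test_full_subset_explains_everything(self, rng):
        R = random_correlation(5, rng)
        assert pve(R, range(5)) == pytest.approx(100.0, abs=1e-8)

    def test_empty_subset_explains_nothing(self, rng):
        assert pve(random_correlation(4, rng), []) == 0.0

    def test_identity_single_variable(self):
        assert pve(np.eye(4), [2]) == pytest.approx(25.0)

    def test_equals_average_squared_multiple_correlation(self, rng):
        """PVE(S) = 100/p * sum_j R^2(x_j ~ x_S), checked by per-variable OLS."""
        for p in (3, 5, 8):
            R = random_correlation(p, rng)
            X = rng.multivariate_normal(np.zeros(p), R, size=4000)
            # population check using the matrix functional directly
            for _ in range(3):
                k = int(rng.integers(1, p))
                S = sorted(rng.choice(p, size=k, replace=False).tolist())
                r2_sum = 0.0
                Rss_inv = np.linalg.inv(R[np.ix_(S, S)])
                for j in range(p):
                    r = R[np.ix_([j], S)]
                    r2_sum += float((r @ Rss_inv @ r.T).item())
                assert pve(R, S) == pytest.approx(100.0 * r2_sum / p, abs=1e-8)

    @given(st.integers(0, 10**6))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_monotone_in_the_subset(self, seed):
        rng = np.random.default_rng(seed)
        p = 6
        R = random_correlation(p, rng)
        S = sorted(rng.choice(p, size=3, replace=False).tolist())
        extra = int(rng.integers(0, p))
        assert pve(R, sorted(set(S + [extra]))) >= pve(R, S) - 1e-9

    def test_singular_submatrix_uses_pseudoinverse(self):
        R = np.ones((3, 3))  # rank one: duplicated variables
        assert pve(R, [0, 1]) == pytest.approx(100.0, abs=1e-8)


class TestSelection:
    def test_duplicate_avoidance_matches_exhaustive(self, rng):
        # v0 == v1 (r = 1), v2 independent: best 2 blocks are {v0 or v1} + {v2}
        R = np.eye(3)
        R[0, 1] = R[1, 0] = 0.999
        est = _estimate(R)
        blocks = [BatteryBlock(v, (v,)) for v in est.variables]
        sel = select_battery(est, blocks, k=2)
        chosen = set(sel.member_ids)
        assert "v2" in chosen and len(chosen & {"v0", "v1"}) == 1
        # exhaustive confirmation
        best = max(
            itertools.combinations(range(3), 2), key=lambda S: pve(R, list(S))
        )
        assert pve(R, [est.variables.index(v) for v in chosen]) == pytest.approx(pve(R, list(best)), abs=1e-6)

    def test_identity_matrix_cumulative_pve(self):
        est = _estimate(np.eye(6))
        blocks = [BatteryBlock(v, (v,)) for v in est.variables]
        sel = select_battery(est, blocks, k=3)
        assert sel.cumulative_pve == pytest.approx([100 / 6, 200 / 6, 300 / 6])

    @pytest.mark.parametrize("seed", [11, 23, 47])
    def test_greedy_near_exhaustive_for_small_p(self, seed):
        rng = np.random.default_rng(seed)
        p, k = 7, 3
        R = random_correlation(p, rng)
        est = _estimate(R)
        blocks = [BatteryBlock(v, (v,)) for v in est.variables]
        sel = select_battery(est, blocks, k=k)
        all_scores = sorted(
            (pve(R, list(S)) for S in itertools.combinations(range(p), k)), reverse=True
        )
        assert sel.cumulative_pve[-1] >= all_scores[min(2, len(all_scores) - 1)] - 1e-9

    def test_significance_breaks_ties(self):
        est = _estimate(np.eye(4))
        blocks = [BatteryBlock(v, (v,)) for v in est.variables]
        sel = select_battery(est, blocks, k=1, significance={"v2": 0.001})
        assert sel.blocks[0].block_id == "v2"  # all gains tie at 25%; significant wins

    def test_k_too_large_rejected(self):
        est = _estimate(np.eye(2))
        blocks = [BatteryBlock(v, (v,)) for v in est.variables]
        with pytest.raises(ValueError, match="exceeds"):
            select_battery(est, blocks, k=3)

    def test_pve_jointly_near_total(self, rng):
        R = random_correlation(6, rng)
        est = _estimate(R)
        blocks = [BatteryBlock(v, (v,)) for v in est.variables]
        sel = select_battery(est, blocks, k=3)
        assert all(0 <= v <= 100 for v in sel.pve_alone + sel.pve_jointly)
        assert all(b >= a - 1e-9 for a, b in zip(sel.cumulative_pve, sel.cumulative_pve[1:]))


class TestReferenceBattery:
    def test_counts(self):
        ref = reference_battery()
        assert len(ref) == 15
        assert sum(len(b.members) for b in ref) == 21

    def test_members_are_analysis_variables(self):
        cv = set(correlation_variables(build_default_catalogue()))
        for b in reference_battery():
            for m in b.members:
                assert m in cv

    def test_default_blocks_partition_the_variables(self):
        cat = build_default_catalogue()
        blocks = default_battery_blocks(cat)
        members = [m for b in blocks for m in b.members]
        assert len(members) == len(set(members))

    def test_report_identity_and_disjoint(self):
        ref = reference_battery()
        from xdp_progression.battery import BatterySelection

        same = BatterySelection(
            blocks=ref, pve_alone=[0] * 15, pve_jointly=[0] * 15, cumulative_pve=list(range(15))
        )
        df = report_battery(same, ref)
        assert df.attrs["agreement_pct"] == pytest.approx(100.0)
        other = BatterySelection(
            blocks=[BatteryBlock("x", ("updrs1_01",))], pve_alone=[0], pve_jointly=[0], cumulative_pve=[0]
        )
        assert report_battery(other, ref).attrs["agreement_pct"] == 0.0
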