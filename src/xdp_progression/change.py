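"""First-versus-last change testing with signed-rank tests and FDR control.

For every test unit the difference between the last and first observed
values is computed per symptomatic gene-positive subject, with single
imputation at the endpoints (last observation carried forward at the final
visit, next observation carried backward at enrollment). Subjects with
fewer than two observed timepoints for a unit are excluded. Differences are
tested with a Wilcoxon signed-rank test using the reduced-sample rule for
zeros (drop them) and average ranks for ties, and the resulting p-values
are adjusted with the Benjamini-Hochberg step-up procedure.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .catalogue import CPIB_TOTAL_ID, change_testing_variables
from .cohort import Cohort

__all__ = [
    "ChangeTestResult",
    "first_last_pair",
    "wilcoxon_signed_rank",
    "bh_adjust",
    "run_change_tests",
]

# above this effective sample size (or with ties) the normal approximation
# with tie-corrected variance is used; below it, the exact null distribution
EXACT_N_MAX = 25


def first_last_pair(series: list[float | None]) -> tuple[float, float] | None:
    """Endpoint pair (first, last) for one subject's per-visit series.

    The value at the final visit is imputed by last observation carried
    forward; the enrollment value by next observation carried backward.
    Returns ``None`` (excluded) when fewer than two timepoints are observed.
    """
    observed = [v for v in series if v is not None]
    if len(observed) < 2:
        return None
    return observed[0], observed[-1]


def _exact_two_sided_p(ranks: np.ndarray, w_obs: float) -> float:
    """P(|W| >= |w_obs|) under the signed-rank null, by subset-sum DP.

    Equivalent to enumerating all 2^n sign assignments: W+ is the sum of a
    uniformly random subset of the (integer) ranks, and W = 2*W+ - sum(ranks).
    """
    r = ranks.astype(int)
    total = int(r.sum())
    counts = np.zeros(total + 1, dtype=float)
    counts[0] = 1.0
    for ri in r:
        counts[ri:] += counts[: total + 1 - ri]
    w_vals = 2 * np.arange(total + 1) - total
    keep = np.abs(w_vals) >= abs(w_obs) - 1e-12
    return float(counts[keep].sum() / 2.0 ** len(r))


def wilcoxon_signed_rank(differences) -> tuple[float, float | None, int]:
    """Signed-rank test statistic W (sum of signed ranks) and two-sided p.

    Zero differences are excluded (reduced-sample procedure); tied absolute
    differences receive average ranks. The exact null distribution is used
    when the reduced sample is tie-free with n <= 25; otherwise a normal
    approximation with variance sum(rank_i^2) (tie-corrected, no continuity
    correction). Returns ``(nan, None, 0)`` when all differences are zero.
    """
    d = np.asarray(differences, dtype=float)
    if d.size == 0:
        raise ValueError("at least one difference required")
    d = d[d != 0.0]
    n = int(d.size)
    if n == 0:
        return math.nan, None, 0
    ranks = stats.rankdata(np.abs(d), method="average")
    w = float(np.sum(np.sign(d) * ranks))
    has_ties = np.unique(np.abs(d)).size < n
    if n <= EXACT_N_MAX and not has_ties:
        p = _exact_two_sided_p(ranks, w)
    else:
        # signs independent under H0: Var(W) = sum of squared ranks
        sd = math.sqrt(float(np.sum(ranks**2)))
        z = w / sd
        p = float(2.0 * stats.norm.sf(abs(z)))
    return w, min(p, 1.0), n


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone form).

    Sorted ascending, p_adj(k) = min_{j >= k} min(1, p(j) * m / j), mapped
    back to the input order. NaN entries (untestable units) are passed
    through and do not count toward m.
    """
    p = np.asarray(p_values, dtype=float)
    valid = ~np.isnan(p)
    if np.any((p[valid] < 0) | (p[valid] > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    out = np.full(p.shape, np.nan)
    pv = p[valid]
    m = pv.size
    if m:
        order = np.argsort(pv, kind="stable")
        scaled = pv[order] * m / np.arange(1, m + 1)
        adj = np.minimum(1.0, np.minimum.accumulate(scaled[::-1])[::-1])
        res = np.empty(m)
        res[order] = adj
        out[valid] = res
    return out


@dataclass(frozen=True)
class ChangeTestResult:
    test_unit: str
    n_subjects: int
    mean_difference: float
    std_error: float
    w_statistic: float
    p_value: float | None
    p_adjusted: float | None
    significant: bool


def run_change_tests(cohort: Cohort, fdr_level: float = 0.05) -> list[ChangeTestResult]:
    """Run the full change-testing pipeline on symptomatic subjects.

    Returns one result per test unit, sorted by adjusted p-value (testable
    units first). Raises ``ValueError`` when the cohort has no symptomatic
    gene-positive subjects.
    """
    subjects = cohort.subjects_in_group("positive_symptomatic")
    if not subjects:
        raise ValueError("no symptomatic gene-positive subjects in cohort")
    units = change_testing_variables(cohort.catalogue)
    wide = cohort.value_table()
    cpib_items = [m.measure_id for m in cohort.catalogue.core_measures if m.group == "CPIB survey"]
    if cpib_items:
        sums = wide.reindex(columns=cpib_items).sum(axis=1)
        sums[wide.reindex(columns=cpib_items).isna().any(axis=1)] = np.nan
        wide = wide.assign(**{CPIB_TOTAL_ID: sums})

    def unit_series(subject: str, visit_indices, unit: str):
        if unit not in wide.columns:
            return [None] * len(visit_indices)
        col = wide[unit]
        out = []
        for t in visit_indices:
            v = col.get((subject, t), np.nan)
            out.append(None if v is None or (isinstance(v, float) and math.isnan(v)) else float(v))
        return out

    rows: list[dict] = []
    for unit in units:
        diffs = []
        for s in subjects:
            pair = first_last_pair(unit_series(s.subject_id, s.visit_indices, unit))
            if pair is not None:
                diffs.append(pair[1] - pair[0])
        if not diffs:
            rows.append(dict(unit=unit, n=0, mean=math.nan, se=math.nan, w=math.nan, p=None))
            continue
        d = np.asarray(diffs, dtype=float)
        w, p, _ = wilcoxon_signed_rank(d)
        se = float(d.std(ddof=1) / math.sqrt(d.size)) if d.size > 1 else math.nan
        rows.append(dict(unit=unit, n=d.size, mean=float(d.mean()), se=se, w=w, p=p))

    p_in = np.array([math.nan if r["p"] is None else r["p"] for r in rows])
    p_adj = bh_adjust(p_in)
    results = []
    for r, pa in zip(rows, p_adj):
        adj = None if math.isnan(pa) else float(pa)
        results.append(
            ChangeTestResult(
                test_unit=r["unit"],
                n_subjects=r["n"],
                mean_difference=r["mean"],
                std_error=r["se"],
                w_statistic=r["w"],
                p_value=r["p"],
                p_adjusted=adj,
                significant=adj is not None and adj < fdr_level,
            )
        )
    results.sort(key=lambda x: (x.p_adjusted is None, x.p_adjusted, x.test_unit))
    return results
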