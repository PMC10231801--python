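"""Per-category progression rates and clustering of progression patterns.

The global trajectory model gives each symptomatic subject one rate for all
measures. To expose heterogeneity, the model is refitted independently to
each pre-defined category of measures with the ages at onset held fixed at
the global-fit estimates (a common time realignment), yielding a rate
profile Rate_ig per subject i and category g. BMI forms its own category
(log-normal regression) even though it is excluded from the global fit.
Subjects are then compared by the Euclidean distance between their rate
profiles and organized by agglomerative clustering.

The default 13-category scheme maps each battery measure to exactly one
clinically defined symptom domain; it is a stand-in assembled from the
measure groups and the category names used in the study narrative, and is
fully overridable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .catalogue import BMI_ID, MeasureCatalogue
from .cohort import Cohort
from .trajectory import PriorConfig, fit_trajectory

__all__ = [
    "CategoryScheme",
    "RateProfile",
    "default_category_scheme",
    "fit_category_rates",
    "rate_distance_matrix",
    "cluster_subjects",
]


@dataclass
class CategoryScheme:
    """Mapping of measure_ids to named symptom-domain categories."""

    mapping: dict[str, str]  # measure_id -> category name

    def __post_init__(self) -> None:
        if len(self.categories) < 2:
            raise ValueError("need at least two categories")

    @property
    def categories(self) -> list[str]:
        return sorted(set(self.mapping.values()))

    def measures_in(self, category: str) -> list[str]:
        return [m for m, c in self.mapping.items() if c == category]


@dataclass
class RateProfile:
    """One subject's per-category posterior-mean rates and interval half-widths."""

    subject_id: str
    rates: dict[str, float]
    halfwidths: dict[str, float] = field(default_factory=dict)
    intervals: dict[str, tuple[float, float]] = field(default_factory=dict)

    def vector(self, categories: list[str]) -> np.ndarray:
        return np.array([self.rates[c] for c in categories])


def default_category_scheme(catalogue: MeasureCatalogue) -> CategoryScheme:
    """The built-in 13-category scheme, read off the catalogue's category tags.

    Categories: rigidity, tremor (rest), tremor (other), bradykinesia,
    dystonia (limbs), dystonia (axial), speech, swallowing, gait,
    non-motor, daily-living (motor), quantitative oromotor, and BMI.
    """
    mapping = {
        m.measure_id: m.category
        for m in catalogue.measures
        if m.category is not None and (not m.auxiliary or m.measure_id == BMI_ID)
    }
    return CategoryScheme(mapping=mapping)


def fit_category_rates(
    cohort: Cohort,
    fixed_onsets: dict[str, float],
    scheme: CategoryScheme | None = None,
    priors: PriorConfig | None = None,
    global_params: dict[str, dict[str, float]] | None = None,
    n_chains: int = 2,
    n_warmup: int = 200,
    n_draws: int = 300,
    seed: int = 0,
) -> list[RateProfile]:
    """Refit the trajectory model per category with frozen onsets.

    ``fixed_onsets`` maps each symptomatic subject to the onset age from
    the global fit; ``global_params`` carries the global fit's
    posterior-mean measure parameters (``PosteriorSummary.measure_summaries``).
    Measures present there are pinned so every category's Rate_ig lives on
    the global fit's rate scale and profiles are comparable across
    categories; measures absent from the global fit (BMI) are refit freely.
    Categories with no observed data leave the rates at their prior (a
    warning is raised by the underlying fit when sampling is
    uninformative). Returns one profile per subject in ``fixed_onsets``.
    """
    scheme = scheme or default_category_scheme(cohort.catalogue)
    observed = {o.measure_id for o in cohort.observations}
    profiles: dict[str, RateProfile] = {
        sid: RateProfile(subject_id=sid, rates={}, halfwidths={}, intervals={}) for sid in fixed_onsets
    }
    for ci, category in enumerate(scheme.categories):
        measures = [m for m in scheme.measures_in(category) if m in observed]
        if not measures:
            warnings.warn(f"category {category!r}: no observed data; rates revert to the prior")
            for sid in fixed_onsets:
                profiles[sid].rates[category] = 1.0
                profiles[sid].halfwidths[category] = np.nan
                profiles[sid].intervals[category] = (np.nan, np.nan)
            continue
        pinned = (
            {m: global_params[m] for m in measures if m in global_params} if global_params else None
        )
        fit = fit_trajectory(
            cohort,
            priors=priors,
            measure_ids=measures,
            n_chains=n_chains,
            n_warmup=n_warmup,
            n_draws=n_draws,
            seed=int(np.random.default_rng([seed, ci]).integers(2**31 - 1)),
            fixed_onsets=fixed_onsets,
            fixed_measure_params=pinned,
            rhat_threshold=1.05,
        )
        for sid in fixed_onsets:
            if sid in fit.subject_ids:
                i = fit.subject_ids.index(sid)
                lo, hi = fit.rate_interval[i]
                profiles[sid].rates[category] = float(fit.rate_mean[i])
                profiles[sid].halfwidths[category] = float((hi - lo) / 2)
                profiles[sid].intervals[category] = (float(lo), float(hi))
            else:
                profiles[sid].rates[category] = 1.0
                profiles[sid].halfwidths[category] = np.nan
                profiles[sid].intervals[category] = (np.nan, np.nan)
    return [profiles[sid] for sid in fixed_onsets]


def rate_distance_matrix(profiles: list[RateProfile]) -> tuple[np.ndarray, list[str]]:
    """Pairwise Euclidean distances between per-category rate vectors."""
    if not profiles:
        raise ValueError("no profiles supplied")
    categories = sorted(profiles[0].rates)
    for p in profiles:
        if sorted(p.rates) != categories:
            raise ValueError(f"profile {p.subject_id} has mismatched categories")
    M = np.stack([p.vector(categories) for p in profiles])
    diff = M[:, None, :] - M[None, :, :]
    D = np.sqrt((diff**2).sum(axis=2))
    return D, [p.subject_id for p in profiles]


def cluster_subjects(profiles: list[RateProfile], method: str = "average"):
    """Cluster subjects by rate profile; also order them by average rate.

    Returns ``(linkage, leaf_order_ids, by_average_rate_ids)``. The average
    ordering is highest to lowest mean rate across categories, ties broken
    by subject id. Requires at least two subjects.
    """
    if len(profiles) < 2:
        raise ValueError("need at least two subjects to cluster")
    D, ids = rate_distance_matrix(profiles)
    Z = hierarchy.linkage(squareform(D, checks=False), method=method)
    leaf_ids = [ids[i] for i in hierarchy.leaves_list(Z)]
    categories = sorted(profiles[0].rates)
    avg = {p.subject_id: float(np.mean(p.vector(categories))) for p in profiles}
    ordered = sorted(ids, key=lambda s: (-avg[s], s))
    return Z, leaf_ids, ordered


def profiles_frame(profiles: list[RateProfile]) -> pd.DataFrame:
    categories = sorted(profiles[0].rates) if profiles else []
    return pd.DataFrame(
        [{"subject_id": p.subject_id, **{c: p.rates[c] for c in categories}} for p in profiles]
    )
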