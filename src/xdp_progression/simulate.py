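"""Synthetic XDP natural-history cohort generator.

Emulates the structure of the study cohort: 29 symptomatic gene-positive,
7 pre-symptomatic gene-positive and 51 gene-negative men, four visits at
six-month intervals, the full 107-measure battery plus anthropometrics,
repeat-size-dependent true onset with reported onset lagging behind it, a
log-normal per-subject rate of progression, and ~9% missing entries
(missing completely at random).

Every measure is generated from the same observation family the trajectory
model fits (cumulative logit / log-normal / Poisson-softplus), with
covariates Age and Rate_i * [Age - Onset_i]+, so downstream stages can be
validated against the generator's ground truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .catalogue import (
    BMI_ID,
    HEIGHT_ID,
    WEIGHT_ID,
    MeasureCatalogue,
    build_default_catalogue,
)
from .cohort import Cohort, ObservationRecord, SubjectRecord
from .likelihoods import (
    ContinuousParams,
    CountParams,
    OrdinalParams,
    ordinal_category_probs,
    softplus,
    time_since_onset,
)

__all__ = ["SimulationConfig", "GroundTruth", "simulate_cohort", "empirical_onset_repeat_correlation"]

AGE_CENTER = 40.0  # years; linear predictors use age - AGE_CENTER

# left/right analogue items generated with copula-correlated latents
_BILATERAL_PAIRS = [
    ("updrs3_03_rigidity_rue", "updrs3_03_rigidity_lue"),
    ("updrs3_03_rigidity_rle", "updrs3_03_rigidity_lle"),
    ("updrs3_04_finger_tapping_right", "updrs3_04_finger_tapping_left"),
    ("updrs3_05_hand_movements_right", "updrs3_05_hand_movements_left"),
    ("updrs3_06_pronation_supination_right", "updrs3_06_pronation_supination_left"),
    ("updrs3_07_toe_tapping_right", "updrs3_07_toe_tapping_left"),
    ("updrs3_08_leg_agility_right", "updrs3_08_leg_agility_left"),
    ("updrs3_15_postural_tremor_right", "updrs3_15_postural_tremor_left"),
    ("updrs3_16_kinetic_tremor_right", "updrs3_16_kinetic_tremor_left"),
    ("updrs3_17_rest_tremor_rue", "updrs3_17_rest_tremor_lue"),
    ("updrs3_17_rest_tremor_rle", "updrs3_17_rest_tremor_lle"),
    ("bfm_move_right_arm", "bfm_move_left_arm"),
    ("bfm_move_right_leg", "bfm_move_left_leg"),
]
_PAIR_MATE = {a: b for a, b in _BILATERAL_PAIRS} | {b: a for a, b in _BILATERAL_PAIRS}

# typical log-scale location and residual sd for the continuous measures
_CONTINUOUS_SCALE = {
    "tongue_strength": (3.8, 0.25),
    "mpt": (2.7, 0.30),
    "ddk_duration_ba": (1.8, 0.30),
    "ddk_duration_da": (1.8, 0.30),
    "ddk_duration_ka": (1.8, 0.30),
    "ddk_duration_amr": (1.8, 0.30),
    "swallow_duration": (1.5, 0.35),
    WEIGHT_ID: (4.1, 0.05),
    HEIGHT_ID: (5.1, 0.0),  # subject-level constant
}


@dataclass
class SimulationConfig:
    """Cohort simulator settings; defaults mirror the study conditions."""

    n_symptomatic: int = 29
    n_presymptomatic: int = 7
    n_negative: int = 51
    n_visits: int = 4
    visit_spacing: float = 0.5  # years
    # true onset ~ Normal(intercept + slope * repeat_size, sd)
    onset_intercept: float = 79.0
    onset_slope: float = -1.1
    onset_sd: float = 5.0
    repeat_size_range: tuple[int, int] = (35, 55)
    # reported onset = true onset + lag, lag ~ Normal(mean, sd) truncated at 0
    report_lag_mean: float = 7.5
    report_lag_sd: float = 3.0
    rate_log_sd: float = 0.5  # Rate_i ~ LogNormal(0, rate_log_sd)
    category_rate_log_sd: float = 0.0  # Rate_ig ~ LogNormal(log Rate_i, .)
    # planted heterogeneity: subject_id -> {category: multiplier on Rate_ig}
    category_rate_multipliers: dict = field(default_factory=dict)
    # magnitude ranges for the progression coefficient beta2, by value kind
    beta_rate_ordinal: tuple[float, float] = (0.15, 0.40)
    beta_rate_continuous: tuple[float, float] = (0.02, 0.06)
    beta_rate_count: tuple[float, float] = (0.30, 0.90)
    beta_rate_ddk: tuple[float, float] = (0.05, 0.15)
    null_effects: bool = False  # zero every beta2 (no progression anywhere)
    # restrict progression effects to these measures (None = all progress)
    effect_subset: list[str] | None = None
    # Gaussian-copula correlation between left/right analogue items, matching
    # the strong bilateral dependence seen in this disease
    bilateral_rho: float = 0.8
    missing_fraction: float = 0.09
    seed: int = 0

    def validate(self) -> None:
        if min(self.n_symptomatic, self.n_presymptomatic, self.n_negative) < 0:
            raise ValueError("cohort sizes must be >= 0")
        if not 0 <= self.missing_fraction < 1:
            raise ValueError("missing_fraction must be in [0, 1)")
        if self.visit_spacing <= 0:
            raise ValueError("visit_spacing must be > 0")
        if self.n_visits < 1:
            raise ValueError("need at least one visit")


@dataclass
class GroundTruth:
    """Simulation-side copies of every latent the analyses estimate."""

    onsets: dict[str, float]  # true onset age, gene-positive subjects
    rates: dict[str, float]  # global Rate_i, gene-positive subjects
    category_rates: dict[str, dict[str, float]]  # Rate_ig
    measure_params: dict[str, object]  # measure_id -> params dataclass
    config: SimulationConfig = field(repr=False, default=None)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for sid, onset in self.onsets.items():
            row = {"subject_id": sid, "true_onset": onset, "true_rate": self.rates[sid]}
            for cat, r in self.category_rates.get(sid, {}).items():
                row[f"rate_{cat}"] = r
            rows.append(row)
        return pd.DataFrame(rows)


def _draw_measure_params(spec, rng: np.random.Generator, config: SimulationConfig):
    """True parameters for one measure, with severity-consistent beta2 sign."""
    suppress = config.null_effects or (
        config.effect_subset is not None and spec.measure_id not in config.effect_subset
    )
    if spec.value_kind == "ordinal":
        k = spec.n_levels
        first = rng.uniform(0.5, 2.0)
        incr = rng.uniform(0.5, 1.5, size=k - 2)
        thresholds = tuple(np.concatenate([[first], first + np.cumsum(incr)]))
        beta_age = rng.normal(-0.01, 0.01)
        # worsening shifts mass to worse categories: cumulative-low logits fall
        mag = rng.uniform(*config.beta_rate_ordinal)
        beta_rate = -spec.severity_direction * mag
        if suppress:
            beta_rate = 0.0
        return OrdinalParams(thresholds=thresholds, beta_age=beta_age, beta_rate=beta_rate)
    if spec.value_kind == "positive_real":
        loc, sigma = _CONTINUOUS_SCALE.get(spec.measure_id, (rng.uniform(1.0, 4.0), 0.25))
        sigma = max(sigma, 1e-6)
        beta_age = rng.normal(0.0, 0.003)
        mag = rng.uniform(*config.beta_rate_continuous)
        beta_rate = spec.severity_direction * mag
        if spec.measure_id == HEIGHT_ID:
            beta_age = 0.0
            beta_rate = 0.0
        if suppress:
            beta_rate = 0.0
        return ContinuousParams(alpha=loc, beta_age=beta_age, beta_rate=beta_rate, sigma=sigma)
    # counts
    if spec.offset_link == "unit":
        alpha = rng.uniform(15.0, 25.0)
        mag = rng.uniform(*config.beta_rate_count)
        beta_age = rng.normal(0.0, 0.05)
    else:
        alpha = rng.uniform(2.5, 6.0)  # syllables per second against the duration offset
        mag = rng.uniform(*config.beta_rate_ddk)
        beta_age = rng.normal(0.0, 0.01)
    beta_rate = spec.severity_direction * mag
    if suppress:
        beta_rate = 0.0
    return CountParams(alpha=alpha, beta_age=beta_age, beta_rate=beta_rate)


def _truncnorm_pos(rng, mean, sd, size=None):
    """Normal(mean, sd) truncated below at 0, by resampling."""
    x = rng.normal(mean, sd, size=size)
    bad = x < 0
    while np.any(bad):
        x = np.where(bad, rng.normal(mean, sd, size=np.shape(x)), x)
        bad = x < 0
    return x


def simulate_cohort(
    config: SimulationConfig | None = None,
    catalogue: MeasureCatalogue | None = None,
) -> tuple[Cohort, GroundTruth]:
    """Generate a cohort and its ground-truth latents, reproducibly from seed."""
    config = config or SimulationConfig()
    config.validate()
    catalogue = catalogue or build_default_catalogue()
    rng = np.random.default_rng(config.seed)

    subjects: list[SubjectRecord] = []
    onsets: dict[str, float] = {}
    rates: dict[str, float] = {}
    category_rates: dict[str, dict[str, float]] = {}
    categories = sorted({m.category for m in catalogue.measures if m.category})

    lo, hi = config.repeat_size_range
    fam_counter = 0

    def next_family(rng) -> str:
        nonlocal fam_counter
        fam_counter += 1
        return f"F{fam_counter:03d}"

    def add_positive(i: int, symptomatic: bool, family_id: str) -> None:
        sid = f"P{i:03d}" if symptomatic else f"A{i:03d}"
        repeat = int(rng.integers(lo, hi + 1))
        true_onset = rng.normal(config.onset_intercept + config.onset_slope * repeat, config.onset_sd)
        true_onset = max(true_onset, 20.0)
        rate = float(np.exp(rng.normal(0.0, config.rate_log_sd)))
        if symptomatic:
            lag = float(_truncnorm_pos(rng, config.report_lag_mean, config.report_lag_sd))
            reported = true_onset + lag
            duration = float(_truncnorm_pos(rng, 4.0, 2.0)) + 0.5
            age0 = reported + duration
            initial = "dystonia" if rng.random() < 23 / 29 else "parkinsonism"
        else:
            reported = None
            age0 = max(18.0, true_onset - rng.uniform(2.0, 12.0))
            initial = "none"
        ages = [age0 + t * config.visit_spacing + rng.normal(0.0, 0.02) for t in range(config.n_visits)]
        ages = list(np.maximum.accumulate(np.asarray(ages)))  # keep strictly increasing
        for t in range(1, len(ages)):
            if ages[t] <= ages[t - 1]:
                ages[t] = ages[t - 1] + 1e-3
        subjects.append(
            SubjectRecord(
                subject_id=sid,
                genotype_group="positive_symptomatic" if symptomatic else "positive_presymptomatic",
                reported_onset=reported,
                repeat_size=repeat,
                family_id=family_id,
                initial_symptom=initial,
                visits=list(enumerate(ages)),
            )
        )
        onsets[sid] = float(true_onset)
        rates[sid] = rate
        category_rates[sid] = {
            c: float(np.exp(rng.normal(np.log(rate), config.category_rate_log_sd)))
            if config.category_rate_log_sd > 0
            else rate
            for c in categories
        }
        for c, mult in config.category_rate_multipliers.get(sid, {}).items():
            category_rates[sid][c] = category_rates[sid].get(c, rate) * float(mult)

    i = 0
    while i < config.n_symptomatic:
        fam = next_family(rng)
        size = min(int(rng.integers(1, 4)), config.n_symptomatic - i)
        for _ in range(size):
            add_positive(i + 1, symptomatic=True, family_id=fam)
            i += 1
    for i in range(config.n_presymptomatic):
        add_positive(i + 1, symptomatic=False, family_id=next_family(rng))
    for i in range(config.n_negative):
        sid = f"N{i + 1:03d}"
        age0 = max(18.0, rng.normal(36.2, 12.6))
        ages = [age0 + t * config.visit_spacing + rng.normal(0.0, 0.02) for t in range(config.n_visits)]
        for t in range(1, len(ages)):
            if ages[t] <= ages[t - 1]:
                ages[t] = ages[t - 1] + 1e-3
        subjects.append(
            SubjectRecord(
                subject_id=sid,
                genotype_group="negative",
                family_id=next_family(rng),
                visits=list(enumerate(ages)),
            )
        )

    measure_params = {m.measure_id: _draw_measure_params(m, rng, config) for m in catalogue.measures if m.measure_id != BMI_ID}

    observations: list[ObservationRecord] = []
    heights: dict[str, float] = {}
    for s in subjects:
        heights[s.subject_id] = float(np.exp(rng.normal(5.1, 0.04)))
        weight_effect = rng.normal(0.0, 0.12)  # stable per-subject weight offset
        onset_i = onsets.get(s.subject_id, math.inf)
        for t, age in s.visits:
            age_c = age - AGE_CENTER
            tso = float(time_since_onset(age, onset_i)) if math.isfinite(onset_i) else 0.0
            durations: dict[str, float] = {}
            stashed_u: dict[str, float] = {}  # copula uniforms for pair mates
            rho = float(np.clip(config.bilateral_rho, -0.999, 0.999))
            for spec in catalogue.measures:
                if spec.measure_id == BMI_ID:
                    continue
                params = measure_params[spec.measure_id]
                rate = (
                    category_rates.get(s.subject_id, {}).get(spec.category, rates.get(s.subject_id, 1.0))
                    if spec.category
                    else rates.get(s.subject_id, 1.0)
                )
                if spec.measure_id == HEIGHT_ID:
                    value = heights[s.subject_id]
                elif spec.value_kind == "ordinal":
                    probs = ordinal_category_probs(params, spec.ordinal_levels, age_c, rate, onset_i - AGE_CENTER)
                    if spec.measure_id in stashed_u:
                        u = stashed_u.pop(spec.measure_id)
                    elif spec.measure_id in _PAIR_MATE and rho != 0.0:
                        z1 = rng.standard_normal()
                        z2 = rho * z1 + math.sqrt(1 - rho**2) * rng.standard_normal()
                        u = float(stats.norm.cdf(z1))
                        stashed_u[_PAIR_MATE[spec.measure_id]] = float(stats.norm.cdf(z2))
                    else:
                        u = float(rng.random())
                    idx = int(np.searchsorted(np.cumsum(probs), u, side="right"))
                    value = float(spec.ordinal_levels[min(idx, spec.n_levels - 1)])
                elif spec.value_kind == "positive_real":
                    mu = params.alpha + params.beta_age * age_c + params.beta_rate * rate * tso
                    if spec.measure_id == WEIGHT_ID:
                        mu += weight_effect
                    value = float(np.exp(rng.normal(mu, max(params.sigma, 1e-9))))
                else:  # count
                    offset = 1.0 if spec.offset_link == "unit" else durations[spec.offset_link]
                    eta = params.alpha + params.beta_age * age_c + params.beta_rate * rate * tso
                    value = float(rng.poisson(offset * float(softplus(eta))))
                if spec.value_kind == "positive_real":
                    durations[spec.measure_id] = value
                observations.append(ObservationRecord(s.subject_id, t, spec.measure_id, value))
            # BMI derived from weight and height for internal consistency
            w = next(
                o.value
                for o in observations[::-1]
                if o.subject_id == s.subject_id and o.visit_index == t and o.measure_id == WEIGHT_ID
            )
            bmi = w / (heights[s.subject_id] / 100.0) ** 2
            observations.append(ObservationRecord(s.subject_id, t, BMI_ID, float(bmi)))

    # MCAR masking; DDK counts lose their offset when the paired duration is masked
    if config.missing_fraction > 0:
        maskable = [
            i
            for i, o in enumerate(observations)
            if o.measure_id != HEIGHT_ID
        ]
        n_drop = int(round(config.missing_fraction * len(maskable)))
        drop = set(rng.choice(maskable, size=n_drop, replace=False).tolist())
        dropped_durations = {
            (observations[i].subject_id, observations[i].visit_index, observations[i].measure_id)
            for i in drop
            if observations[i].measure_id.startswith("ddk_duration_")
        }
        dropped_weights = {
            (observations[i].subject_id, observations[i].visit_index)
            for i in drop
            if observations[i].measure_id == WEIGHT_ID
        }
        kept = []
        for i, o in enumerate(observations):
            if i in drop:
                continue
            spec = catalogue[o.measure_id]
            if spec.offset_link != "unit" and (o.subject_id, o.visit_index, spec.offset_link) in dropped_durations:
                continue  # count unusable without its exposure offset
            if o.measure_id == BMI_ID and (o.subject_id, o.visit_index) in dropped_weights:
                continue
            kept.append(o)
        observations = kept

    cohort = Cohort(catalogue=catalogue, subjects=subjects, observations=observations)
    truth = GroundTruth(
        onsets=onsets,
        rates=rates,
        category_rates=category_rates,
        measure_params=measure_params,
        config=config,
    )
    return cohort, truth


def empirical_onset_repeat_correlation(cohort: Cohort) -> float:
    """Sample correlation between reported onset and SVA repeat size.

    Diagnostic for generator calibration; the study reports a strong
    negative association on real data. Requires at least three symptomatic
    subjects with both fields and non-constant repeat sizes.
    """
    pairs = [
        (s.reported_onset, s.repeat_size)
        for s in cohort.subjects_in_group("positive_symptomatic")
        if s.reported_onset is not None and s.repeat_size is not None
    ]
    if len(pairs) < 3:
        raise ValueError("need >= 3 symptomatic subjects with onset and repeat size")
    onset, repeat = np.asarray(pairs, dtype=float).T
    if np.std(repeat) == 0 or np.std(onset) == 0:
        raise ValueError("zero variance in onset or repeat size")
    return float(np.corrcoef(onset, repeat)[0, 1])
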