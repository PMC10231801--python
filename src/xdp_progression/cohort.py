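"""Cohort data model and delimited-text I/O.

A cohort couples a measure catalogue with subject metadata (genotype group,
reported age at onset, SVA repeat size, family, initial symptom, visit ages)
and the long-format observations Y_ijt. Missing values are represented by
``None`` in memory and by empty fields on disk; no numeric sentinels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .catalogue import MeasureCatalogue, MeasureSpec

__all__ = [
    "GENOTYPE_GROUPS",
    "SubjectRecord",
    "ObservationRecord",
    "Cohort",
    "CohortValidationError",
    "read_cohort",
    "write_cohort",
]

GENOTYPE_GROUPS = ("positive_symptomatic", "positive_presymptomatic", "negative")
INITIAL_SYMPTOMS = ("dystonia", "parkinsonism", "none")


class CohortValidationError(ValueError):
    """Raised when cohort data violate the schema; carries row context."""


@dataclass
class SubjectRecord:
    subject_id: str
    genotype_group: str
    reported_onset: float | None = None
    repeat_size: int | None = None
    family_id: str | None = None
    initial_symptom: str = "none"
    visits: list[tuple[int, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.genotype_group not in GENOTYPE_GROUPS:
            raise CohortValidationError(
                f"subject {self.subject_id}: unknown genotype_group {self.genotype_group!r}"
            )
        if self.initial_symptom not in INITIAL_SYMPTOMS:
            raise CohortValidationError(
                f"subject {self.subject_id}: unknown initial_symptom {self.initial_symptom!r}"
            )
        symptomatic = self.genotype_group == "positive_symptomatic"
        if symptomatic and self.reported_onset is None:
            raise CohortValidationError(
                f"subject {self.subject_id}: symptomatic subjects need a reported onset"
            )
        if not symptomatic and self.reported_onset is not None:
            raise CohortValidationError(
                f"subject {self.subject_id}: reported onset only valid for symptomatic subjects"
            )
        self.visits = sorted(self.visits, key=lambda v: v[0])
        ages = [a for _, a in self.visits]
        if any(a2 <= a1 for a1, a2 in zip(ages, ages[1:])):
            raise CohortValidationError(
                f"subject {self.subject_id}: visit ages must strictly increase"
            )

    @property
    def visit_indices(self) -> list[int]:
        return [t for t, _ in self.visits]

    def age_at(self, visit_index: int) -> float:
        for t, a in self.visits:
            if t == visit_index:
                return a
        raise KeyError(f"subject {self.subject_id} has no visit {visit_index}")


@dataclass(frozen=True)
class ObservationRecord:
    subject_id: str
    visit_index: int
    measure_id: str
    value: float


def _validate_value(spec: MeasureSpec, value: float, context: str) -> None:
    if not math.isfinite(value):
        raise CohortValidationError(f"{context}: non-finite value")
    if spec.value_kind == "ordinal":
        if value not in spec.ordinal_levels:
            raise CohortValidationError(
                f"{context}: value {value} not in ordinal level set {spec.ordinal_levels}"
            )
    elif spec.value_kind == "positive_real":
        if value <= 0:
            raise CohortValidationError(f"{context}: positive_real value must be > 0, got {value}")
    elif spec.value_kind == "count":
        if value < 0 or value != int(value):
            raise CohortValidationError(
                f"{context}: count value must be a non-negative integer, got {value}"
            )


@dataclass
class Cohort:
    catalogue: MeasureCatalogue
    subjects: list[SubjectRecord]
    observations: list[ObservationRecord]

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        subj = {s.subject_id for s in self.subjects}
        if len(subj) != len(self.subjects):
            raise CohortValidationError("duplicate subject_ids")
        visits = {(s.subject_id, t) for s in self.subjects for t in s.visit_indices}
        seen: set[tuple[str, int, str]] = set()
        for i, obs in enumerate(self.observations):
            ctx = f"observation {i} ({obs.subject_id}, visit {obs.visit_index}, {obs.measure_id})"
            if obs.subject_id not in subj:
                raise CohortValidationError(f"{ctx}: unknown subject")
            if (obs.subject_id, obs.visit_index) not in visits:
                raise CohortValidationError(f"{ctx}: subject has no such visit")
            if obs.measure_id not in self.catalogue:
                raise CohortValidationError(f"{ctx}: unknown measure_id")
            key = (obs.subject_id, obs.visit_index, obs.measure_id)
            if key in seen:
                raise CohortValidationError(f"{ctx}: duplicate observation")
            seen.add(key)
            _validate_value(self.catalogue[obs.measure_id], obs.value, ctx)

    # ------------------------------------------------------------------
    def subject(self, subject_id: str) -> SubjectRecord:
        for s in self.subjects:
            if s.subject_id == subject_id:
                return s
        raise KeyError(subject_id)

    def subjects_in_group(self, *groups: str) -> list[SubjectRecord]:
        return [s for s in self.subjects if s.genotype_group in groups]

    def observations_frame(self) -> pd.DataFrame:
        """Long-format DataFrame of observations."""
        return pd.DataFrame(
            [
                {
                    "subject_id": o.subject_id,
                    "visit_index": o.visit_index,
                    "measure_id": o.measure_id,
                    "value": o.value,
                }
                for o in self.observations
            ],
            columns=["subject_id", "visit_index", "measure_id", "value"],
        )

    def value_table(self, measure_ids: list[str] | None = None) -> pd.DataFrame:
        """Wide table indexed by (subject_id, visit_index); NaN = missing."""
        df = self.observations_frame()
        wide = df.pivot(index=["subject_id", "visit_index"], columns="measure_id", values="value")
        # ensure every subject-visit row exists even if fully unobserved
        idx = pd.MultiIndex.from_tuples(
            [(s.subject_id, t) for s in self.subjects for t in s.visit_indices],
            names=["subject_id", "visit_index"],
        )
        wide = wide.reindex(idx)
        if measure_ids is not None:
            wide = wide.reindex(columns=measure_ids)
        return wide

    def series(self, subject_id: str, measure_id: str) -> list[float | None]:
        """Per-visit values for one subject and measure (None = missing)."""
        s = self.subject(subject_id)
        lut = {
            (o.visit_index): o.value
            for o in self.observations
            if o.subject_id == subject_id and o.measure_id == measure_id
        }
        return [lut.get(t) for t in s.visit_indices]


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def _opt_float(x) -> float | None:
    if x is None or (isinstance(x, float) and math.isnan(x)) or x == "":
        return None
    return float(x)


def _opt_str(x) -> str | None:
    if x is None or (isinstance(x, float) and math.isnan(x)) or x == "":
        return None
    return str(x)


def read_cohort(
    measurements_path: str | Path,
    subjects_path: str | Path,
    visits_path: str | Path,
    catalogue: MeasureCatalogue,
) -> Cohort:
    """Read a cohort from delimited text files.

    ``measurements_path``: columns subject_id, visit_index, measure_id, value.
    ``subjects_path``: columns subject_id, genotype_group, reported_onset,
    repeat_size, family_id, initial_symptom.
    ``visits_path``: long companion table with columns subject_id,
    visit_index, age.

    Invalid rows raise :class:`CohortValidationError` with row numbers.
    """
    subj_df = pd.read_csv(subjects_path, dtype={"subject_id": str, "family_id": str}, float_precision="round_trip")
    visits_df = pd.read_csv(visits_path, dtype={"subject_id": str}, float_precision="round_trip")
    meas_df = pd.read_csv(measurements_path, dtype={"subject_id": str, "measure_id": str}, float_precision="round_trip")

    visit_lut: dict[str, list[tuple[int, float]]] = {}
    for row in visits_df.itertuples(index=True):
        visit_lut.setdefault(str(row.subject_id), []).append(
            (int(row.visit_index), float(row.age))
        )

    subjects = []
    for row in subj_df.itertuples(index=True):
        try:
            subjects.append(
                SubjectRecord(
                    subject_id=str(row.subject_id),
                    genotype_group=str(row.genotype_group),
                    reported_onset=_opt_float(row.reported_onset),
                    repeat_size=(
                        None
                        if _opt_float(row.repeat_size) is None
                        else int(float(row.repeat_size))
                    ),
                    family_id=_opt_str(row.family_id),
                    initial_symptom=_opt_str(row.initial_symptom) or "none",
                    visits=visit_lut.get(str(row.subject_id), []),
                )
            )
        except CohortValidationError as e:
            raise CohortValidationError(f"subjects row {row.Index + 2}: {e}") from None

    observations = []
    for row in meas_df.itertuples(index=True):
        value = _opt_float(row.value)
        if value is None:
            continue  # empty field = missing: simply not recorded
        observations.append(
            ObservationRecord(
                subject_id=str(row.subject_id),
                visit_index=int(row.visit_index),
                measure_id=str(row.measure_id),
                value=value,
            )
        )
    try:
        return Cohort(catalogue=catalogue, subjects=subjects, observations=observations)
    except CohortValidationError as e:
        raise CohortValidationError(f"measurements file {measurements_path}: {e}") from None


def write_cohort(
    cohort: Cohort,
    measurements_path: str | Path,
    subjects_path: str | Path,
    visits_path: str | Path,
) -> None:
    """Write a cohort to the three delimited text files (UTF-8, headers)."""
    cohort.observations_frame().to_csv(measurements_path, index=False, float_format="%.17g")
    pd.DataFrame(
        [
            {
                "subject_id": s.subject_id,
                "genotype_group": s.genotype_group,
                "reported_onset": s.reported_onset,
                "repeat_size": s.repeat_size,
                "family_id": s.family_id,
                "initial_symptom": s.initial_symptom,
            }
            for s in cohort.subjects
        ]
    ).to_csv(subjects_path, index=False, float_format="%.17g")
    pd.DataFrame(
        [
            {"subject_id": s.subject_id, "visit_index": t, "age": a}
            for s in cohort.subjects
            for t, a in s.visits
        ]
    ).to_csv(visits_path, index=False, float_format="%.17g")
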