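"""Clinical measure catalogue for the XDP natural-history battery.

The study battery contains 107 individual measures of three value kinds:
ordinal rating-scale items (MDS-UPDRS Parts 1-3, BFM disability and movement
scales, EAT-10, CPIB), positive real-valued instrumental measures (tongue
strength, maximum phonation time, DDK task durations, swallow duration) and
non-negative integer counts (lip strength after rounding, DDK syllable counts
with the paired task duration as exposure offset).

Anthropometric variables (height, weight, BMI) are carried as auxiliary
measures: they are observed like any other measure but are not part of the
107-measure battery, which lets weight serve as an external validation
variable for the trajectory model.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

__all__ = [
    "MeasureSpec",
    "MeasureCatalogue",
    "build_default_catalogue",
    "change_testing_variables",
    "correlation_variables",
    "CPIB_TOTAL_ID",
    "WEIGHT_ID",
    "HEIGHT_ID",
    "BMI_ID",
    "REPEAT_SIZE_ID",
    "REPORTED_ONSET_ID",
]

VALUE_KINDS = ("ordinal", "positive_real", "count")

# identifiers for derived / auxiliary analysis variables
CPIB_TOTAL_ID = "cpib_total"
WEIGHT_ID = "weight"
HEIGHT_ID = "height"
BMI_ID = "bmi"
REPEAT_SIZE_ID = "repeat_size"
REPORTED_ONSET_ID = "reported_onset"


@dataclass(frozen=True)
class MeasureSpec:
    """Schema of a single clinical measure.

    Parameters
    ----------
    measure_id
        Short unique identifier, e.g. ``"updrs3_02_facial_expression"``.
    label
        Human-readable name.
    group
        Battery group name (one of the study's measure groups).
    value_kind
        ``"ordinal"``, ``"positive_real"`` or ``"count"``.
    ordinal_levels
        Strictly increasing category values c_1..c_K; empty unless ordinal.
    severity_direction
        +1 if higher values indicate greater severity, -1 otherwise.
    offset_link
        For count measures, ``"unit"`` or the measure_id of the duration
        measure supplying the Poisson exposure offset.
    category
        Rate-heterogeneity category name, or ``None`` if unassigned.
    auxiliary
        True for measures outside the 107-measure battery (height, weight,
        BMI).
    """

    measure_id: str
    label: str
    group: str
    value_kind: str
    ordinal_levels: tuple[float, ...] = ()
    severity_direction: int = 1
    offset_link: str = "unit"
    category: str | None = None
    auxiliary: bool = False

    def __post_init__(self) -> None:
        if self.value_kind not in VALUE_KINDS:
            raise ValueError(f"unknown value_kind {self.value_kind!r}")
        if self.value_kind == "ordinal":
            if len(self.ordinal_levels) < 2:
                raise ValueError(f"{self.measure_id}: ordinal needs K >= 2 levels")
            if any(a >= b for a, b in zip(self.ordinal_levels, self.ordinal_levels[1:])):
                raise ValueError(f"{self.measure_id}: ordinal_levels must strictly increase")
        elif self.ordinal_levels:
            raise ValueError(f"{self.measure_id}: ordinal_levels only valid for ordinal kind")
        if self.offset_link != "unit" and self.value_kind != "count":
            raise ValueError(f"{self.measure_id}: offset_link requires value_kind count")
        if self.severity_direction not in (1, -1):
            raise ValueError("severity_direction must be +1 or -1")

    @property
    def n_levels(self) -> int:
        return len(self.ordinal_levels)


@dataclass
class MeasureCatalogue:
    """Ordered collection of measure specs plus auxiliary-variable flags."""

    measures: list[MeasureSpec] = field(default_factory=list)
    auxiliary_variables: dict[str, bool] = field(
        default_factory=lambda: {
            REPEAT_SIZE_ID: True,
            REPORTED_ONSET_ID: True,
            HEIGHT_ID: True,
            WEIGHT_ID: True,
            BMI_ID: True,
        }
    )

    def __post_init__(self) -> None:
        ids = [m.measure_id for m in self.measures]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate measure_ids: {dupes}")
        by_id = {m.measure_id: m for m in self.measures}
        for m in self.measures:
            if m.offset_link != "unit":
                link = by_id.get(m.offset_link)
                if link is None:
                    raise ValueError(f"{m.measure_id}: offset_link {m.offset_link!r} not in catalogue")
                if link.value_kind != "positive_real":
                    raise ValueError(f"{m.measure_id}: offset measure must be positive_real")

    def __len__(self) -> int:
        return len(self.core_measures)

    def __getitem__(self, measure_id: str) -> MeasureSpec:
        for m in self.measures:
            if m.measure_id == measure_id:
                return m
        raise KeyError(measure_id)

    def __contains__(self, measure_id: str) -> bool:
        return any(m.measure_id == measure_id for m in self.measures)

    @property
    def core_measures(self) -> list[MeasureSpec]:
        """The battery measures (excludes auxiliary anthropometrics)."""
        return [m for m in self.measures if not m.auxiliary]

    @property
    def measure_ids(self) -> list[str]:
        return [m.measure_id for m in self.measures]

    def group_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for m in self.core_measures:
            counts[m.group] = counts.get(m.group, 0) + 1
        return counts

    def by_kind(self, kind: str) -> list[MeasureSpec]:
        return [m for m in self.core_measures if m.value_kind == kind]

    def without_group(self, group: str) -> "MeasureCatalogue":
        return MeasureCatalogue(
            measures=[m for m in self.measures if m.group != group],
            auxiliary_variables=dict(self.auxiliary_variables),
        )


# ---------------------------------------------------------------------------
# default catalogue (the study's Table-1 inventory)
# ---------------------------------------------------------------------------

_LEVELS_0_4 = (0.0, 1.0, 2.0, 3.0, 4.0)
_LEVELS_0_3 = (0.0, 1.0, 2.0, 3.0)
_LEVELS_BFM_WALK = (0.0, 1.0, 2.0, 3.0, 4.0, 6.0)
# BFM movement items score provoking x severity factors, giving 10 distinct values
_LEVELS_BFM_MOVE = (0.0, 1.0, 2.0, 3.0, 4.0, 6.0, 8.0, 9.0, 12.0, 16.0)

_UPDRS1_ITEMS = [
    ("01", "cognitive impairment"),
    ("02", "hallucinations and psychosis"),
    ("03", "depressed mood"),
    ("04", "anxious mood"),
    ("05", "apathy"),
    ("06", "dopamine dysregulation syndrome"),
    ("07", "sleep problems"),
    ("08", "daytime sleepiness"),
    ("09", "pain and other sensations"),
    ("10", "urinary problems"),
    ("11", "constipation problems"),
    ("12", "light headedness on standing"),
    ("13", "fatigue"),
]

_UPDRS2_ITEMS = [
    ("01", "speech", "speech"),
    ("02", "saliva and drooling", "swallowing"),
    ("03", "chewing and swallowing", "swallowing"),
    ("04", "eating tasks", "daily_living_motor"),
    ("05", "dressing", "daily_living_motor"),
    ("06", "hygiene", "daily_living_motor"),
    ("07", "handwriting", "daily_living_motor"),
    ("08", "doing hobbies", "daily_living_motor"),
    ("09", "turning in bed", "daily_living_motor"),
    ("10", "tremor", "tremor_other"),
    ("11", "getting out of bed", "daily_living_motor"),
    ("12", "walking and balance", "gait"),
    ("13", "freezing", "gait"),
]

# (suffix, label, category) — the standard 33-item MDS-UPDRS Part 3 split
_UPDRS3_ITEMS = [
    ("01_speech", "3.1: speech", "speech"),
    ("02_facial_expression", "3.2: facial expression", "bradykinesia"),
    ("03_rigidity_neck", "3.3: rigidity - neck", "rigidity"),
    ("03_rigidity_rue", "3.3: rigidity - RUE", "rigidity"),
    ("03_rigidity_lue", "3.3: rigidity - LUE", "rigidity"),
    ("03_rigidity_rle", "3.3: rigidity - RLE", "rigidity"),
    ("03_rigidity_lle", "3.3: rigidity - LLE", "rigidity"),
    ("04_finger_tapping_right", "3.4: finger tapping - right hand", "bradykinesia"),
    ("04_finger_tapping_left", "3.4: finger tapping - left hand", "bradykinesia"),
    ("05_hand_movements_right", "3.5: hand movements - right hand", "bradykinesia"),
    ("05_hand_movements_left", "3.5: hand movements - left hand", "bradykinesia"),
    ("06_pronation_supination_right", "3.6: pronation-supination - right hand", "bradykinesia"),
    ("06_pronation_supination_left", "3.6: pronation-supination - left hand", "bradykinesia"),
    ("07_toe_tapping_right", "3.7: toe tapping - right foot", "bradykinesia"),
    ("07_toe_tapping_left", "3.7: toe tapping - left foot", "bradykinesia"),
    ("08_leg_agility_right", "3.8: leg agility - right leg", "bradykinesia"),
    ("08_leg_agility_left", "3.8: leg agility - left leg", "bradykinesia"),
    ("09_arising_from_chair", "3.9: arising from chair", "gait"),
    ("10_gait", "3.10: gait", "gait"),
    ("11_freezing_of_gait", "3.11: freezing of gait", "gait"),
    ("12_postural_stability", "3.12: postural stability", "gait"),
    ("13_posture", "3.13: posture", "gait"),
    ("14_global_spontaneity", "3.14: global spontaneity of movement", "bradykinesia"),
    ("15_postural_tremor_right", "3.15: postural tremor - right hand", "tremor_other"),
    ("15_postural_tremor_left", "3.15: postural tremor - left hand", "tremor_other"),
    ("16_kinetic_tremor_right", "3.16: kinetic tremor - right hand", "tremor_other"),
    ("16_kinetic_tremor_left", "3.16: kinetic tremor - left hand", "tremor_other"),
    ("17_rest_tremor_rue", "3.17: rest tremor amplitude - RUE", "tremor_rest"),
    ("17_rest_tremor_lue", "3.17: rest tremor amplitude - LUE", "tremor_rest"),
    ("17_rest_tremor_rle", "3.17: rest tremor amplitude - RLE", "tremor_rest"),
    ("17_rest_tremor_lle", "3.17: rest tremor amplitude - LLE", "tremor_rest"),
    ("17_rest_tremor_lip_jaw", "3.17: rest tremor amplitude - lip/jaw", "tremor_rest"),
    ("18_constancy_rest_tremor", "3.18: constancy of rest tremor", "tremor_rest"),
]

_BFM_DISABILITY_ITEMS = [
    ("speech", "speech"),
    ("handwriting", "daily_living_motor"),
    ("feeding", "daily_living_motor"),
    ("eating_swallowing", "swallowing"),
    ("hygiene", "daily_living_motor"),
    ("dressing", "daily_living_motor"),
]

_BFM_MOVEMENT_ITEMS = [
    ("eyes", "dystonia_axial"),
    ("mouth", "dystonia_axial"),
    ("speech_swallowing", "speech"),
    ("neck", "dystonia_axial"),
    ("right_arm", "dystonia_limbs"),
    ("left_arm", "dystonia_limbs"),
    ("trunk", "dystonia_axial"),
    ("right_leg", "dystonia_limbs"),
    ("left_leg", "dystonia_limbs"),
]

_DDK_TASKS = ["ba", "da", "ka", "amr"]


def build_default_catalogue() -> MeasureCatalogue:
    """Build the full 107-measure battery plus auxiliary anthropometrics.

    Group sizes: MDS-UPDRS Part 1 (13), Part 2 (13), Part 3 (33), BFM
    disability (6), BFM disability walking (1), BFM movement (9), EAT-10
    (10), CPIB (10), lip strength (1), tongue strength (1), maximum
    phonation time (1), DDK counts (4), DDK durations (4), swallow
    duration (1).
    """
    measures: list[MeasureSpec] = []

    for suffix, label in _UPDRS1_ITEMS:
        measures.append(
            MeasureSpec(
                measure_id=f"updrs1_{suffix}",
                label=f"MDS-UPDRS 1.{int(suffix)}: {label}",
                group="MDS-UPDRS Part 1",
                value_kind="ordinal",
                ordinal_levels=_LEVELS_0_4,
                category="non_motor",
            )
        )
    for suffix, label, cat in _UPDRS2_ITEMS:
        measures.append(
            MeasureSpec(
                measure_id=f"updrs2_{suffix}",
                label=f"MDS-UPDRS 2.{int(suffix)}: {label}",
                group="MDS-UPDRS Part 2",
                value_kind="ordinal",
                ordinal_levels=_LEVELS_0_4,
                category=cat,
            )
        )
    for suffix, label, cat in _UPDRS3_ITEMS:
        measures.append(
            MeasureSpec(
                measure_id=f"updrs3_{suffix}",
                label=f"MDS-UPDRS {label}",
                group="MDS-UPDRS Part 3",
                value_kind="ordinal",
                ordinal_levels=_LEVELS_0_4,
                category=cat,
            )
        )
    for name, cat in _BFM_DISABILITY_ITEMS:
        measures.append(
            MeasureSpec(
                measure_id=f"bfm_dis_{name}",
                label=f"BFM disability: {name.replace('_', '/')}",
                group="BFM disability scale",
                value_kind="ordinal",
                ordinal_levels=_LEVELS_0_4,
                category=cat,
            )
        )
    measures.append(
        MeasureSpec(
            measure_id="bfm_dis_walking",
            label="BFM disability: walking",
            group="BFM disability scale: walking",
            value_kind="ordinal",
            ordinal_levels=_LEVELS_BFM_WALK,
            category="gait",
        )
    )
    for name, cat in _BFM_MOVEMENT_ITEMS:
        measures.append(
            MeasureSpec(
                measure_id=f"bfm_move_{name}",
                label=f"BFM movement: {name.replace('_', ' ')}",
                group="BFM movement scale",
                value_kind="ordinal",
                ordinal_levels=_LEVELS_BFM_MOVE,
                category=cat,
            )
        )
    for q in range(1, 11):
        measures.append(
            MeasureSpec(
                measure_id=f"eat10_q{q:02d}",
                label=f"EAT-10: Q{q}",
                group="EAT-10 survey",
                value_kind="ordinal",
                ordinal_levels=_LEVELS_0_4,
                category="swallowing",
            )
        )
    for q in range(1, 11):
        measures.append(
            MeasureSpec(
                measure_id=f"cpib_q{q:02d}",
                label=f"CPIB: Q{q}",
                group="CPIB survey",
                value_kind="ordinal",
                ordinal_levels=_LEVELS_0_3,
                severity_direction=-1,
                category="speech",
            )
        )
    measures.append(
        MeasureSpec(
            measure_id="lip_strength",
            label="Lip strength (kPa, rounded)",
            group="Lip strength",
            value_kind="count",
            severity_direction=-1,
            category="oromotor_quantitative",
        )
    )
    measures.append(
        MeasureSpec(
            measure_id="tongue_strength",
            label="Tongue strength (kPa)",
            group="Tongue strength",
            value_kind="positive_real",
            severity_direction=-1,
            category="oromotor_quantitative",
        )
    )
    measures.append(
        MeasureSpec(
            measure_id="mpt",
            label="Maximum phonation time (s)",
            group="Maximum phonation time",
            value_kind="positive_real",
            severity_direction=-1,
            category="speech",
        )
    )
    # durations precede counts so offsets resolve on a single pass
    for task in _DDK_TASKS:
        measures.append(
            MeasureSpec(
                measure_id=f"ddk_duration_{task}",
                label=f"DDK duration: {task.upper()} (s)",
                group="DDK durations",
                value_kind="positive_real",
                severity_direction=-1,
                category="oromotor_quantitative",
            )
        )
    for task in _DDK_TASKS:
        measures.append(
            MeasureSpec(
                measure_id=f"ddk_count_{task}",
                label=f"DDK count: {task.upper()}",
                group="DDK counts",
                value_kind="count",
                severity_direction=-1,
                offset_link=f"ddk_duration_{task}",
                category="oromotor_quantitative",
            )
        )
    measures.append(
        MeasureSpec(
            measure_id="swallow_duration",
            label="Swallow duration (s)",
            group="Swallow duration",
            value_kind="positive_real",
            category="swallowing",
        )
    )

    # auxiliary anthropometrics, outside the 107-measure battery
    measures.append(
        MeasureSpec(
            measure_id=WEIGHT_ID,
            label="Weight (kg)",
            group="Anthropometrics",
            value_kind="positive_real",
            severity_direction=-1,
            auxiliary=True,
        )
    )
    measures.append(
        MeasureSpec(
            measure_id=HEIGHT_ID,
            label="Height (cm)",
            group="Anthropometrics",
            value_kind="positive_real",
            severity_direction=-1,
            auxiliary=True,
        )
    )
    measures.append(
        MeasureSpec(
            measure_id=BMI_ID,
            label="Body mass index (kg/m^2)",
            group="Anthropometrics",
            value_kind="positive_real",
            severity_direction=-1,
            category="bmi",
            auxiliary=True,
        )
    )
    return MeasureCatalogue(measures=measures)


def change_testing_variables(catalogue: MeasureCatalogue) -> list[str]:
    """Test units for first-versus-last change testing.

    The 10 CPIB items are collapsed into a single summed unit (they are very
    strongly correlated) and participant weight is appended, yielding 99
    units for the default catalogue.
    """
    units: list[str] = []
    cpib_seen = False
    for m in catalogue.core_measures:
        if m.group == "CPIB survey":
            if not cpib_seen:
                units.append(CPIB_TOTAL_ID)
                cpib_seen = True
        else:
            units.append(m.measure_id)
    units.append(WEIGHT_ID)
    return units


def correlation_variables(catalogue: MeasureCatalogue) -> list[str]:
    """Variables entering the correlation analysis.

    The change-testing units plus three subject-level constants: SVA repeat
    size, reported age at onset and height (102 for the default catalogue).
    """
    out = change_testing_variables(catalogue)
    out.extend([REPEAT_SIZE_ID, REPORTED_ONSET_ID, HEIGHT_ID])
    if len(set(out)) != len(out):
        raise ValueError("correlation variable identifiers are not unique")
    return out
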