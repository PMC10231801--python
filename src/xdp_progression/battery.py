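"""Principal-variables selection of a minimal assessment battery.

Given an estimated correlation matrix R over the analysis variables, the
percentage of total variance a subset S explains is the McCabe-style
functional

    PVE(S) = 100 * trace(R[:,S] R[S,S]^{-1} R[S,:]) / p

which equals the average squared multiple correlation of every variable
regressed on S, times 100. Measures that are naturally acquired in pairs
(left/right analogues, a DDK count with its duration) are grouped into
blocks selected jointly. Selection is greedy forward maximisation of the
incremental PVE, with a preference for blocks containing measures that
changed significantly over the study used to break near-ties.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .catalogue import WEIGHT_ID, MeasureCatalogue, change_testing_variables
from .correlation import CorrelationEstimate

__all__ = [
    "BatteryBlock",
    "BatterySelection",
    "pve",
    "select_battery",
    "report_battery",
    "default_battery_blocks",
    "reference_battery",
]


@dataclass(frozen=True)
class BatteryBlock:
    block_id: str
    members: tuple[str, ...]

    def __post_init__(self) -> None:
        if not 1 <= len(self.members) <= 2:
            raise ValueError("blocks contain one or two member variables")


@dataclass
class BatterySelection:
    blocks: list[BatteryBlock]
    pve_alone: list[float]  # percent explained by each block by itself
    pve_jointly: list[float]  # leave-one-out increment within the final set
    cumulative_pve: list[float]

    def __post_init__(self) -> None:
        c = self.cumulative_pve
        if any(b < a - 1e-9 for a, b in zip(c, c[1:])):
            raise ValueError("cumulative PVE must be non-decreasing")

    @property
    def member_ids(self) -> list[str]:
        return [m for b in self.blocks for m in b.members]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "block": [b.block_id for b in self.blocks],
                "members": [";".join(b.members) for b in self.blocks],
                "pve_alone_pct": self.pve_alone,
                "pve_jointly_pct": self.pve_jointly,
                "cumulative_pve_pct": self.cumulative_pve,
            }
        )


def pve(R: np.ndarray, subset_idx) -> float:
    """Percent of total variance of all p variables explained by a subset.

    Uses a pseudo-inverse when the subset submatrix is singular. An empty
    subset explains 0%.
    """
    R = np.asarray(R, dtype=float)
    if R.size == 0:
        raise ValueError("empty correlation matrix")
    idx = np.asarray(list(subset_idx), dtype=int)
    p = R.shape[0]
    if idx.size == 0:
        return 0.0
    Rss = R[np.ix_(idx, idx)]
    Rs = R[:, idx]
    try:
        sol = np.linalg.solve(Rss, Rs.T)
    except np.linalg.LinAlgError:
        sol = np.linalg.pinv(Rss) @ Rs.T
    if not np.all(np.isfinite(sol)):
        sol = np.linalg.pinv(Rss) @ Rs.T
    return float(100.0 * np.trace(Rs @ sol) / p)


def select_battery(
    estimate: CorrelationEstimate,
    blocks: list[BatteryBlock],
    k: int,
    significance: dict[str, float] | None = None,
    fdr_level: float = 0.05,
    tie_tol: float = 1e-6,
) -> BatterySelection:
    """Greedy forward selection of k blocks maximizing incremental PVE.

    ``significance`` maps variable ids to BH-adjusted p-values; among
    candidate blocks whose incremental PVE ties within ``tie_tol``, a block
    containing a significant measure (adjusted p < ``fdr_level``) is
    preferred. Significance is a tie-break only, never a hard filter.
    """
    if k > len(blocks):
        raise ValueError(f"k={k} exceeds the {len(blocks)} available blocks")
    var_index = {v: i for i, v in enumerate(estimate.variables)}
    seen: set[str] = set()
    for b in blocks:
        for m in b.members:
            if m not in var_index:
                raise ValueError(f"block {b.block_id}: member {m!r} not in correlation estimate")
            if m in seen:
                raise ValueError(f"member {m!r} appears in multiple blocks")
            seen.add(m)
    significance = significance or {}

    def block_significant(b: BatteryBlock) -> bool:
        return any(significance.get(m, 1.0) < fdr_level for m in b.members)

    R = estimate.mean
    selected: list[BatteryBlock] = []
    selected_idx: list[int] = []
    cumulative: list[float] = []
    remaining = list(blocks)
    current = 0.0
    for _ in range(k):
        gains = []
        for b in remaining:
            idx = selected_idx + [var_index[m] for m in b.members]
            gains.append(pve(R, idx) - current)
        best_gain = max(gains)
        tied = [b for b, g in zip(remaining, gains) if g >= best_gain - tie_tol]
        winners = [b for b in tied if block_significant(b)] or tied
        # deterministic: first in block order among the winners
        choice = winners[0]
        selected.append(choice)
        selected_idx.extend(var_index[m] for m in choice.members)
        current = pve(R, selected_idx)
        cumulative.append(current)
        remaining.remove(choice)

    alone = [pve(R, [var_index[m] for m in b.members]) for b in selected]
    jointly = []
    for b in selected:
        without = [var_index[m] for bb in selected if bb is not b for m in bb.members]
        jointly.append(current - pve(R, without))
    return BatterySelection(blocks=selected, pve_alone=alone, pve_jointly=jointly, cumulative_pve=cumulative)


def default_battery_blocks(catalogue: MeasureCatalogue) -> list[BatteryBlock]:
    """Blocks over the correlation variables, pairing natural left/right
    analogues and each DDK count with its duration."""
    pairs = [
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
        ("ddk_count_ba", "ddk_duration_ba"),
        ("ddk_count_da", "ddk_duration_da"),
        ("ddk_count_ka", "ddk_duration_ka"),
        ("ddk_count_amr", "ddk_duration_amr"),
    ]
    paired = {m for pr in pairs for m in pr}
    blocks = [BatteryBlock(block_id=a, members=(a, b)) for a, b in pairs]
    for unit in change_testing_variables(catalogue):
        if unit not in paired:
            blocks.append(BatteryBlock(block_id=unit, members=(unit,)))
    return blocks


def reference_battery() -> list[BatteryBlock]:
    """The study's proposed minimal battery: 15 groups, 21 measures."""
    return [
        BatteryBlock("weight", (WEIGHT_ID,)),
        BatteryBlock("bfm_dis_speech", ("bfm_dis_speech",)),
        BatteryBlock("bfm_dis_feeding", ("bfm_dis_feeding",)),
        BatteryBlock("bfm_dis_dressing", ("bfm_dis_dressing",)),
        BatteryBlock("bfm_move_arms", ("bfm_move_right_arm", "bfm_move_left_arm")),
        BatteryBlock("bfm_move_legs", ("bfm_move_right_leg", "bfm_move_left_leg")),
        BatteryBlock("updrs3_02_facial_expression", ("updrs3_02_facial_expression",)),
        BatteryBlock("updrs3_03_rigidity_upper", ("updrs3_03_rigidity_rue", "updrs3_03_rigidity_lue")),
        BatteryBlock("updrs3_07_toe_tapping", ("updrs3_07_toe_tapping_right", "updrs3_07_toe_tapping_left")),
        BatteryBlock("updrs3_11_freezing_of_gait", ("updrs3_11_freezing_of_gait",)),
        BatteryBlock("updrs3_15_postural_tremor", ("updrs3_15_postural_tremor_right", "updrs3_15_postural_tremor_left")),
        BatteryBlock("updrs3_18_constancy_rest_tremor", ("updrs3_18_constancy_rest_tremor",)),
        BatteryBlock("eat10_q01", ("eat10_q01",)),
        BatteryBlock("eat10_q08", ("eat10_q08",)),
        BatteryBlock("ddk_ka", ("ddk_count_ka", "ddk_duration_ka")),
    ]


def report_battery(selection: BatterySelection, reference: list[BatteryBlock] | None = None) -> pd.DataFrame:
    """Tabulate the data-driven selection against the reference battery.

    Agreement counts measures (not blocks) present in both batteries.
    """
    reference = reference if reference is not None else reference_battery()
    sel_members = set(selection.member_ids)
    ref_members = {m for b in reference for m in b.members}
    rows = []
    for b in reference:
        rows.append(
            {
                "battery": "reference",
                "block": b.block_id,
                "members": ";".join(b.members),
                "in_other": all(m in sel_members for m in b.members),
            }
        )
    for b in selection.blocks:
        rows.append(
            {
                "battery": "selected",
                "block": b.block_id,
                "members": ";".join(b.members),
                "in_other": all(m in ref_members for m in b.members),
            }
        )
    df = pd.DataFrame(rows)
    shared = len(sel_members & ref_members)
    df.attrs["n_shared_measures"] = shared
    df.attrs["agreement_pct"] = 100.0 * shared / len(ref_members) if ref_members else 0.0
    return df
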