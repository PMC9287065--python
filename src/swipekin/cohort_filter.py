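"""Swipe- and participant-level inclusion cascade and sensitivity subset.

Food-to-plate swipes enter the analysis sample only after a fixed cascade
of exclusions, applied in order so each swipe carries exactly one primary
exclusion reason:

1. ``multiple_touch`` — simultaneous gestures, no unique path;
2. ``too_few_samples`` — fewer than five samples, derivatives undefined;
3. ``sub_min_distance`` — displacement shorter than the shortest possible
   food-to-plate gap in the game layout;
4. ``mt_outlier`` — movement time above 2.0 s;
5. ``dist_outlier`` — target distance above 70 mm;
6. ``straightness`` — straightness index above 1.5.

Participants are retained when their food-to-plate swipes make up at least
10% of all swipes during gameplay, i.e. when they engaged with the task.
The sensitivity subset additionally requires under 5 mm of path covered
before the first velocity minimum and after the last one, screening out
swipes whose kinematic form is not a single aimed movement.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "FilterParams",
    "ExclusionReport",
    "EXCLUSION_ORDER",
    "apply_swipe_exclusions",
    "apply_participant_inclusion",
    "sensitivity_subset",
]

EXCLUSION_ORDER = (
    "multiple_touch",
    "too_few_samples",
    "sub_min_distance",
    "mt_outlier",
    "dist_outlier",
    "straightness",
)


@dataclass(frozen=True)
class FilterParams:
    """Thresholds of the exclusion cascade (defaults are the study rules)."""

    mt_max: float = 2.0               # s
    dist_max: float = 70.0            # mm
    straightness_max: float = 1.5
    min_samples: int = 5
    participant_goal_ratio: float = 0.10
    sensitivity_margin: float = 5.0   # mm
    min_distance: float = 13.48       # mm; shortest food-to-plate gap
    literal_participant_rule: bool = False

    def __post_init__(self) -> None:
        for name in ("mt_max", "dist_max", "straightness_max", "min_samples",
                     "participant_goal_ratio", "sensitivity_margin", "min_distance"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class ExclusionReport:
    """Auditable outcome of the exclusion cascade."""

    counts: pd.DataFrame            # rows: reason + retained; columns: total and per group
    retained: pd.DataFrame          # surviving swipe rows
    audit: pd.DataFrame             # per-swipe: gesture_id, reason ('' if retained)
    retained_participants: list[str] = field(default_factory=list)

    @property
    def n_input(self) -> int:
        return len(self.audit)

    @property
    def n_retained(self) -> int:
        return len(self.retained)


def _first_reason(row: pd.Series, params: FilterParams) -> str:
    validity = row.get("validity", "valid")
    if validity == "multiple_touch":
        return "multiple_touch"
    if validity == "too_few_samples" or row.get("n_samples", params.min_samples) < params.min_samples:
        return "too_few_samples"
    if row["target_distance"] < params.min_distance:
        return "sub_min_distance"
    if row["MT"] > params.mt_max:
        return "mt_outlier"
    if row["target_distance"] > params.dist_max:
        return "dist_outlier"
    if row["straightness"] > params.straightness_max:
        return "straightness"
    return ""


def apply_swipe_exclusions(
    kin: pd.DataFrame,
    params: FilterParams | None = None,
) -> ExclusionReport:
    """Run the swipe-level exclusion cascade on a kinematics table.

    ``kin`` must carry MT, target_distance and straightness columns plus a
    ``validity`` column from parsing (and optionally ``n_samples`` and a
    ``group`` column for the per-group breakdown).  Each swipe is
    attributed to the first rule that fires, in cascade order; counts per
    reason sum to the input total.
    """
    params = params or FilterParams()
    if "validity" not in kin.columns:
        raise ValueError("kinematics table lacks the 'validity' column from parsing")
    reasons = kin.apply(_first_reason, axis=1, params=params)
    audit_cols = ["participant_id", "gesture_id"] if "gesture_id" in kin.columns else ["participant_id"]
    audit = kin[audit_cols].copy()
    audit["reason"] = reasons.values

    groups = sorted(kin["group"].unique()) if "group" in kin.columns else []
    rows = []
    for reason in EXCLUSION_ORDER + ("retained",):
        mask = (reasons == "") if reason == "retained" else (reasons == reason)
        row = {"reason": reason, "total": int(mask.sum())}
        for g in groups:
            row[str(g)] = int((mask & (kin["group"] == g)).sum())
        rows.append(row)
    counts = pd.DataFrame(rows).set_index("reason")
    retained = kin.loc[reasons == ""].copy()
    return ExclusionReport(counts=counts, retained=retained, audit=audit)


def apply_participant_inclusion(
    swipe_totals: pd.DataFrame,
    params: FilterParams | None = None,
) -> list[str]:
    """Participants retained by the 10% goal-directed engagement rule.

    ``swipe_totals`` has one row per participant with columns
    ``total_swipes`` (all gestures during gameplay) and ``goal_swipes``
    (food-to-plate swipes).  A participant is retained when
    goal_swipes / total_swipes >= 0.10; the boundary ratio counts as
    retained.  Participants with zero recorded swipes are excluded.

    The printed wording of the rule ("excluded ... participants who made
    at least 10%") reads backwards relative to its evident intent of
    keeping engaged players; set ``literal_participant_rule`` in
    :class:`FilterParams` to apply the literal direction instead.
    """
    params = params or FilterParams()
    required = {"total_swipes", "goal_swipes"}
    if not required.issubset(swipe_totals.columns):
        raise ValueError(f"swipe_totals needs columns {sorted(required)}")
    retained = []
    for row in swipe_totals.itertuples():
        if row.total_swipes <= 0:
            continue
        ratio = row.goal_swipes / row.total_swipes
        keep = ratio < params.participant_goal_ratio if params.literal_participant_rule \
            else ratio >= params.participant_goal_ratio
        if keep:
            retained.append(str(row.Index))
    return retained


def sensitivity_subset(
    kin: pd.DataFrame,
    params: FilterParams | None = None,
) -> pd.DataFrame:
    """Stricter subset for sensitivity analysis.

    Keeps swipes with under ``sensitivity_margin`` mm of path covered both
    before the first velocity minimum and after the last one.  A margin of
    zero (the unit starts at touch onset / ends at touch end) passes
    trivially — the criterion applies only where a margin exists.
    """
    params = params or FilterParams()
    for col in ("pre_first_min_dist", "post_last_min_dist"):
        if col not in kin.columns:
            raise ValueError(f"kinematics table lacks '{col}'")
    pre = kin["pre_first_min_dist"].fillna(0.0)
    post = kin["post_last_min_dist"].fillna(0.0)
    mask = (pre < params.sensitivity_margin) & (post < params.sensitivity_margin)
    return kin.loc[mask].copy()
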