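"""Swipe-level kinematic outcome variables.

From a smoothed trajectory, its speed profile and movement units, derive:

* MT — movement time, touch begin to touch end (s);
* PV — global peak speed (mm/s), TTPV — time from touch begin to PV (s);
* %Dec — percentage of MT elapsing after PV (the deceleration phase);
* PV1 — peak speed of the first movement unit; PV1-b — whether PV falls
  in the first unit (a marker of feedforward, chained control);
* MU — movement-unit count; MU-APV — units after PV (corrective
  submovements under feedback control);
* target distance (straight-line start-to-end displacement, binned into
  six 10-mm ordinal categories), path length and the straightness index.

Target distance uses the raw (pre-filter) start and end touch positions so
the covariate reflects where the finger actually landed; path length and
the sensitivity margins use the filtered path.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from swipekin.preprocess import Trajectory, VelocityProfile
from swipekin.segmentation import MovementUnit, pv_in_first_unit, units_after_pv

__all__ = [
    "SwipeKinematics",
    "DIST_LABELS",
    "compute_features",
    "dist_category",
    "dist_label",
    "straightness",
    "path_length",
]

#: Ordinal distance-bin labels; category k covers [10k, 10k+10) mm except
#: the top bin, closed at 70 mm (the longest admissible swipe).
DIST_LABELS = {1: "10-20", 2: "20-30", 3: "30-40", 4: "40-50", 5: "50-60", 6: "60-70"}

DIST_MIN_MM = 10.0
DIST_MAX_MM = 70.0


@dataclass
class SwipeKinematics:
    """All outcome variables and covariates for one swipe."""

    participant_id: str
    gesture_id: str
    MT: float
    PV: float
    TTPV: float
    PV1: float
    PV1_b: bool
    pct_dec: float
    MU: int
    MU_APV: int
    target_distance: float
    dist_cat: int | None
    path_length: float
    straightness: float
    pre_first_min_dist: float
    post_last_min_dist: float
    flagged: bool = False


def dist_category(target_distance: float) -> int:
    """Ordinal 10-mm distance bin, 1 ("10-20") through 6 ("60-70").

    Bins are half-open [lower, upper) except the top bin, which is closed
    at 70 mm.  Distances outside (10, 70] should have been excluded
    upstream and raise.
    """
    d = float(target_distance)
    if d > DIST_MAX_MM:
        raise ValueError(f"target distance {d:.1f} mm exceeds the 70-mm bound")
    if d < DIST_MIN_MM or d <= 0:
        raise ValueError(f"target distance {d:.1f} mm below the shortest bin")
    if d == DIST_MAX_MM:
        return 6
    return int((d - DIST_MIN_MM) // 10) + 1


def dist_label(category: int) -> str:
    return DIST_LABELS[category]


def path_length(x: np.ndarray, y: np.ndarray) -> float:
    """Distance moved: sum of inter-sample Euclidean steps."""
    return float(np.sum(np.hypot(np.diff(x), np.diff(y))))


def straightness(traj: Trajectory) -> float:
    """Straightness index: distance moved over start-to-end displacement.

    1 for a perfectly straight path; invariant to rotation, translation
    and uniform scaling of the trajectory.
    """
    chord = float(np.hypot(traj.x[-1] - traj.x[0], traj.y[-1] - traj.y[0]))
    if chord <= 0:
        raise ValueError("zero start-to-end displacement: not a goal-directed swipe")
    return path_length(traj.x, traj.y) / chord


def _segment_path(x: np.ndarray, y: np.ndarray, i0: int, i1: int) -> float:
    if i1 <= i0:
        return 0.0
    return path_length(x[i0:i1 + 1], y[i0:i1 + 1])


def compute_features(
    traj: Trajectory,
    vel: VelocityProfile,
    units: list[MovementUnit],
    raw_start: tuple[float, float] | None = None,
    raw_end: tuple[float, float] | None = None,
) -> SwipeKinematics:
    """Assemble the swipe-level outcome record.

    ``traj`` is the smoothed trajectory; ``raw_start``/``raw_end`` are the
    first and last recorded touch positions in mm (defaulting to the
    smoothed endpoints when not supplied).  PV is the first sample
    attaining the global maximum speed; %Dec is computed from global PV
    time.  A swipe whose speed profile is degenerate (all zero) or whose
    PV falls outside every unit is returned flagged rather than dropped,
    so the exclusion cascade can account for it.
    """
    s = np.asarray(vel.speed, dtype=float)
    if len(s) != len(traj.t):
        raise ValueError("trajectory and velocity profile lengths differ")
    if not units:
        raise ValueError("at least one movement unit is required")
    mt = float(traj.t[-1] - traj.t[0])
    if mt <= 0:
        raise ValueError(f"non-positive movement time: {mt}")

    pv_idx = int(np.argmax(s))  # first occurrence breaks ties
    pv = float(s[pv_idx])
    ttpv = float(traj.t[pv_idx] - traj.t[0])
    flagged = pv <= 0.0

    try:
        pv1_b = pv_in_first_unit(units, pv_idx)
        mu_apv = units_after_pv(units, pv_idx)
    except ValueError:
        # PV outside all units: an edge-dominated profile.  Fall back to
        # peak-position counting and flag the record for auditing.
        flagged = True
        pv1_b = pv_idx <= units[0].end_idx
        mu_apv = sum(1 for u in units if u.peak_idx > pv_idx)

    x0, y0 = raw_start if raw_start is not None else (traj.x[0], traj.y[0])
    x1, y1 = raw_end if raw_end is not None else (traj.x[-1], traj.y[-1])
    target = float(np.hypot(x1 - x0, y1 - y0))
    plen = path_length(traj.x, traj.y)
    try:
        cat = dist_category(target)
    except ValueError:
        cat = None

    n = len(s)
    return SwipeKinematics(
        participant_id=traj.participant_id,
        gesture_id=traj.gesture_id,
        MT=mt,
        PV=pv,
        TTPV=ttpv,
        PV1=float(units[0].peak_speed),
        PV1_b=bool(pv1_b),
        pct_dec=100.0 * (mt - ttpv) / mt,
        MU=len(units),
        MU_APV=int(mu_apv),
        target_distance=target,
        dist_cat=cat,
        path_length=plen,
        straightness=plen / target if target > 0 else np.nan,
        pre_first_min_dist=_segment_path(traj.x, traj.y, 0, units[0].start_idx),
        post_last_min_dist=_segment_path(traj.x, traj.y, units[-1].end_idx, n - 1),
        flagged=flagged or target <= 0,
    )
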