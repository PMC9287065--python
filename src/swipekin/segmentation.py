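"""Movement-unit segmentation of swipe speed profiles.

A movement unit (MU) is one acceleration-deceleration phase of the speed
profile: a velocity maximum with its flanking minima.  Candidate maxima are
retained only if (a) the velocity change across the unit — the rise from
the preceding minimum plus the fall to the following minimum — totals at
least 8 mm/s, and (b) the maximum exceeds 5% of the swipe's global peak
velocity.  Rejected maxima are merged into their larger neighbouring unit
by deleting the higher of their two boundary minima, iterating until every
retained unit satisfies both criteria.

The first unit starts at the first velocity minimum or at touch onset if
speed rises from the start; the last unit ends at the last velocity minimum
or at touch end if speed falls to it.  Any initial deceleration before the
first minimum, or final acceleration after the last minimum, belongs to no
unit — the path covered there is reported separately as the sensitivity
margins used to screen atypical swipes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

__all__ = [
    "MovementUnit",
    "SegmentationParams",
    "find_local_extrema",
    "segment_units",
    "units_after_pv",
    "pv_in_first_unit",
]


@dataclass(frozen=True)
class MovementUnit:
    """One acceleration-deceleration phase of the speed profile."""

    start_idx: int
    peak_idx: int
    end_idx: int
    peak_speed: float
    rise: float  # peak speed minus speed at the preceding minimum
    fall: float  # peak speed minus speed at the following minimum

    def __post_init__(self) -> None:
        if not (self.start_idx <= self.peak_idx <= self.end_idx):
            raise ValueError(f"unit landmarks out of order: {self}")
        if self.rise < 0 or self.fall < 0:
            raise ValueError(f"negative rise/fall: {self}")


@dataclass(frozen=True)
class SegmentationParams:
    """Criteria for retaining a candidate velocity maximum.

    ``min_cumulative_change`` is the minimum summed velocity change
    (rise + fall) across a unit, in mm/s.  ``min_peak_fraction`` is the
    fraction of the swipe's global peak velocity a maximum must exceed.
    ``cumulative_rule`` selects whether the velocity-change criterion
    applies to rise and fall summed (default) or to each separately — a
    switch kept for sensitivity analysis, since published MU definitions
    differ on this point.
    """

    min_cumulative_change: float = 8.0
    min_peak_fraction: float = 0.05
    cumulative_rule: Literal["sum", "each"] = "sum"

    def __post_init__(self) -> None:
        if self.min_cumulative_change <= 0 or self.min_peak_fraction <= 0:
            raise ValueError("segmentation thresholds must be positive")
        if self.min_peak_fraction >= 1:
            raise ValueError("min_peak_fraction must be below 1")


def _compress_runs(s: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Collapse runs of equal consecutive values to their midpoint index."""
    n = len(s)
    starts = [0]
    for i in range(1, n):
        if s[i] != s[i - 1]:
            starts.append(i)
    starts.append(n)
    mids = np.array(
        [(starts[k] + starts[k + 1] - 1) // 2 for k in range(len(starts) - 1)],
        dtype=int,
    )
    return mids, s[mids]


def find_local_extrema(speed: np.ndarray) -> list[tuple[int, str]]:
    """Locate the alternating minima/maxima of a speed profile.

    Returns an ordered, strictly alternating list of (index, "min"|"max").
    Plateaus collapse to their midpoint sample.  The series start is
    included as a boundary minimum when speed rises from it, and the end
    when speed falls to it, so that every interior maximum has flanking
    minima.  A profile that only decelerates into its first minimum (or
    accelerates out of its last) contributes no boundary minimum at that
    end; that stretch belongs to no unit.
    """
    s = np.asarray(speed, dtype=float)
    n = len(s)
    if n < 3:
        return []
    mids, vals = _compress_runs(s)
    extrema: list[tuple[int, str]] = []
    for k in range(1, len(vals) - 1):
        if vals[k] > vals[k - 1] and vals[k] > vals[k + 1]:
            extrema.append((int(mids[k]), "max"))
        elif vals[k] < vals[k - 1] and vals[k] < vals[k + 1]:
            extrema.append((int(mids[k]), "min"))
    if extrema and extrema[0][1] == "max":
        extrema.insert(0, (0, "min"))
    if extrema and extrema[-1][1] == "max":
        extrema.append((n - 1, "min"))
    return extrema


def segment_units(
    speed: np.ndarray,
    params: SegmentationParams | None = None,
) -> list[MovementUnit]:
    """Decompose a speed profile into movement units.

    Always returns at least one unit: when no candidate maximum survives
    (or none exists, e.g. a monotone or all-zero profile) a single
    degenerate unit spanning the whole series is returned, with its peak at
    the first global speed maximum.

    The 5%-of-PV criterion is evaluated against the global peak speed of
    the full profile, computed before any peak rejection.  When a candidate
    fails either criterion the weakest candidate (smallest rise + fall) is
    merged first: its higher boundary minimum is deleted so the bump joins
    its larger neighbour, and both criteria are re-evaluated until stable.
    """
    params = params or SegmentationParams()
    s = np.asarray(speed, dtype=float)
    n = len(s)
    pv = float(np.max(s)) if n else 0.0
    peak_floor = params.min_peak_fraction * pv

    extrema = find_local_extrema(s)
    mins = [i for i, kind in extrema if kind == "min"]
    peaks = [i for i, kind in extrema if kind == "max"]

    if not peaks:
        peak_idx = int(np.argmax(s)) if n else 0
        return [
            MovementUnit(0, peak_idx, n - 1 if n else 0, pv,
                         rise=pv - float(s[0]) if n else 0.0,
                         fall=pv - float(s[-1]) if n else 0.0)
        ]
    # alternation guarantees len(mins) == len(peaks) + 1
    assert len(mins) == len(peaks) + 1, "extrema sequence not alternating"

    def criteria(j: int) -> tuple[float, bool]:
        rise = s[peaks[j]] - s[mins[j]]
        fall = s[peaks[j]] - s[mins[j + 1]]
        if params.cumulative_rule == "sum":
            big_enough = rise + fall >= params.min_cumulative_change
        else:
            big_enough = (rise >= params.min_cumulative_change
                          and fall >= params.min_cumulative_change)
        return rise + fall, big_enough and s[peaks[j]] > peak_floor

    while len(peaks) > 1:
        scored = [(criteria(j), j) for j in range(len(peaks))]
        failing = [(total, j) for (total, ok), j in scored if not ok]
        if not failing:
            break
        _, j = min(failing)  # weakest candidate first; ties by index
        if j == 0:
            drop = 1
        elif j == len(peaks) - 1:
            drop = j
        else:
            # delete the higher of the two boundary minima (tie: the right)
            drop = j if s[mins[j]] > s[mins[j + 1]] else j + 1
        # deleting minimum `drop` merges peaks drop-1 and drop
        a, b = peaks[drop - 1], peaks[drop]
        merged = a if s[a] >= s[b] else b
        peaks[drop - 1:drop + 1] = [merged]
        del mins[drop]

    units = []
    for j, p in enumerate(peaks):
        units.append(
            MovementUnit(
                start_idx=mins[j],
                peak_idx=int(p),
                end_idx=mins[j + 1],
                peak_speed=float(s[p]),
                rise=float(s[p] - s[mins[j]]),
                fall=float(s[p] - s[mins[j + 1]]),
            )
        )
    return units


def _containing_unit(units: list[MovementUnit], pv_idx: int) -> int:
    for j, u in enumerate(units):
        if u.start_idx <= pv_idx <= u.end_idx:
            return j
    raise ValueError(
        f"peak-velocity index {pv_idx} lies outside all movement units "
        "(segmentation inconsistency)"
    )


def units_after_pv(units: list[MovementUnit], pv_idx: int) -> int:
    """Number of movement units occurring after peak velocity (MU-APV).

    Counts units whose peak lies strictly after ``pv_idx``; the unit
    containing PV is not counted.
    """
    j = _containing_unit(units, pv_idx)
    return sum(1 for k, u in enumerate(units) if k != j and u.peak_idx > pv_idx)


def pv_in_first_unit(units: list[MovementUnit], pv_idx: int) -> bool:
    """True iff global peak velocity falls inside the first movement unit."""
    return _containing_unit(units, pv_idx) == 0
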