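"""Parsing of raw touch-event logs into candidate swipes.

A tablet game logs one row per touch event: participant, gesture id,
timestamp, x/y position in device pixels and a touch phase code
(0 = began, 1 = moved, 3 = ended).  This module groups events into
gestures, screens each gesture for structural validity (a began/moved/ended
phase structure with at least five samples), flags gestures that overlap in
time with another gesture of the same participant (multiple touches, whose
path cannot be attributed to a single finger), and classifies swipes as
goal-directed when they start inside the food area of the game layout and
end inside one of the plate regions.
"""

from __future__ import annotations

import enum
import json
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Phase",
    "SwipeValidity",
    "Rect",
    "GameLayout",
    "RawSwipe",
    "ParseResult",
    "parse_touch_log",
    "flag_multiple_touch",
    "classify_goal_directed",
    "default_layout",
]


class Phase(enum.IntEnum):
    """Touch phase codes as logged by the device."""

    BEGAN = 0
    MOVED = 1
    ENDED = 3


class SwipeValidity(str, enum.Enum):
    VALID = "valid"
    MISSING_STRUCTURE = "missing_structure"
    MULTIPLE_TOUCH = "multiple_touch"
    TOO_FEW_SAMPLES = "too_few_samples"


@dataclass(frozen=True)
class Rect:
    """Axis-aligned rectangle, half-open: [x0, x1) x [y0, y1).

    The half-open convention means a point on an edge shared by two
    adjacent rectangles belongs to exactly one of them.
    """

    x0: float
    y0: float
    x1: float
    y1: float

    def __post_init__(self) -> None:
        if not (self.x1 > self.x0 and self.y1 > self.y0):
            raise ValueError(f"degenerate rectangle: {self}")

    def contains(self, x: float, y: float) -> bool:
        return self.x0 <= x < self.x1 and self.y0 <= y < self.y1

    def gap_to(self, other: "Rect") -> float:
        """Euclidean distance between the closed rectangles (0 if they touch)."""
        dx = max(other.x0 - self.x1, self.x0 - other.x1, 0.0)
        dy = max(other.y0 - self.y1, self.y0 - other.y1, 0.0)
        return float(np.hypot(dx, dy))


@dataclass(frozen=True)
class GameLayout:
    """Game-scene geometry in device pixels.

    ``food_area`` is the central region where food items appear;
    ``plates`` are the target regions.  The end area is the union of the
    plate rectangles.
    """

    food_area: Rect
    plates: tuple[Rect, ...]

    def __post_init__(self) -> None:
        if not self.plates:
            raise ValueError("layout needs at least one plate region")
        for p in self.plates:
            if self._rects_overlap(self.food_area, p):
                raise ValueError("food area and plate regions must be disjoint")

    @staticmethod
    def _rects_overlap(a: Rect, b: Rect) -> bool:
        return a.x0 < b.x1 and b.x0 < a.x1 and a.y0 < b.y1 and b.y0 < a.y1

    def in_food_area(self, x: float, y: float) -> bool:
        return self.food_area.contains(x, y)

    def in_end_area(self, x: float, y: float) -> bool:
        return any(p.contains(x, y) for p in self.plates)

    def min_food_plate_gap_px(self) -> float:
        """Smallest food-to-plate separation; the shortest possible
        goal-directed displacement given the layout."""
        return min(self.food_area.gap_to(p) for p in self.plates)

    @classmethod
    def from_json(cls, path_or_text: str) -> "GameLayout":
        try:
            obj = json.loads(path_or_text)
        except json.JSONDecodeError:
            with open(path_or_text) as fh:
                obj = json.load(fh)
        return cls(
            food_area=Rect(*obj["food_area"]),
            plates=tuple(Rect(*p) for p in obj["plates"]),
        )

    def to_json(self) -> str:
        return json.dumps(
            {
                "food_area": [self.food_area.x0, self.food_area.y0,
                              self.food_area.x1, self.food_area.y1],
                "plates": [[p.x0, p.y0, p.x1, p.y1] for p in self.plates],
            }
        )


def default_layout() -> GameLayout:
    """Stylised sharing-game layout on a 2048 x 1536 px canvas.

    A central food rectangle with four plates placed left, right, above and
    below it.  The nearest food-to-plate edge separation is 173 px
    (about 13.5 mm at 326 ppi), which sets the shortest possible
    food-to-plate swipe displacement.
    """
    return GameLayout(
        food_area=Rect(724, 518, 1324, 1018),
        plates=(
            Rect(271, 618, 551, 918),    # left
            Rect(1497, 618, 1777, 918),  # right
            Rect(874, 145, 1174, 345),   # top
            Rect(874, 1191, 1174, 1391), # bottom
        ),
    )


@dataclass
class RawSwipe:
    """One gesture's ordered event stream plus a structural validity flag."""

    participant_id: str
    gesture_id: str
    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    phase: np.ndarray
    validity: SwipeValidity = SwipeValidity.VALID

    @property
    def n_samples(self) -> int:
        return len(self.t)

    @property
    def t_begin(self) -> float:
        return float(self.t[0])

    @property
    def t_end(self) -> float:
        return float(self.t[-1])


@dataclass
class ParseResult:
    """Partition of the input log: every event row ends up either in a
    swipe (valid or invalid) or in the rejects table."""

    swipes: list[RawSwipe]
    rejects: pd.DataFrame = field(default_factory=pd.DataFrame)


DEFAULT_COLUMNS: dict[str, str] = {
    "participant_id": "participant_id",
    "gesture_id": "gesture_id",
    "t": "t",
    "x": "x",
    "y": "y",
    "phase": "phase",
}

_ALLOWED_PHASES = {int(Phase.BEGAN), int(Phase.MOVED), int(Phase.ENDED)}


def _structural_validity(phase: np.ndarray, n: int) -> SwipeValidity:
    if int(phase[0]) != Phase.BEGAN or int(phase[-1]) != Phase.ENDED:
        return SwipeValidity.MISSING_STRUCTURE
    if n < 5:
        return SwipeValidity.TOO_FEW_SAMPLES
    return SwipeValidity.VALID


def parse_touch_log(
    records: pd.DataFrame | str,
    columns: Mapping[str, str] | None = None,
    flag_overlaps: bool = True,
) -> ParseResult:
    """Parse a tabular touch-event stream into :class:`RawSwipe` objects.

    Parameters
    ----------
    records
        Event table or path to a CSV/TSV file.  Required logical columns:
        participant_id, gesture_id, t (s), x, y (device px), phase
        (0/1/3).  If the gesture_id column is absent, gestures are
        reconstructed per participant from the phase sequence: a began
        event opens a gesture, an ended event closes it; a began arriving
        while another gesture is open closes the open gesture as
        structurally invalid.
    columns
        Optional mapping from logical names to actual column names.
    flag_overlaps
        Run :func:`flag_multiple_touch` on the parsed swipes (on by
        default, matching the exclusion of simultaneous gestures).

    Returns
    -------
    ParseResult
        Swipes (one per gesture, events time-sorted, validity assigned)
        and a rejects table of malformed rows with a ``reason`` column.
    """
    if isinstance(records, str):
        sep = "\t" if records.endswith((".tsv", ".tab")) else ","
        records = pd.read_csv(records, sep=sep)
    cols = dict(DEFAULT_COLUMNS)
    if columns:
        cols.update(columns)

    needed = ["participant_id", "t", "x", "y", "phase"]
    missing = [cols[k] for k in needed if cols[k] not in records.columns]
    if missing:
        raise ValueError(f"event log is missing columns: {missing}")

    df = records.rename(columns={v: k for k, v in cols.items()})
    has_gesture_ids = "gesture_id" in df.columns

    rejects: list[dict] = []
    numeric = {}
    for col in ("t", "x", "y", "phase"):
        numeric[col] = pd.to_numeric(df[col], errors="coerce")
    bad = (
        numeric["t"].isna()
        | numeric["x"].isna()
        | numeric["y"].isna()
        | numeric["phase"].isna()
        | (numeric["t"] < 0)
        | ~numeric["phase"].isin(list(_ALLOWED_PHASES))
    )
    for idx in df.index[bad]:
        rejects.append(
            {"row": int(idx), "reason": "malformed row (non-numeric or out-of-range field)"}
        )
    clean = df.loc[~bad].copy()
    for col in ("t", "x", "y", "phase"):
        clean[col] = numeric[col].loc[~bad]

    swipes: list[RawSwipe] = []
    if has_gesture_ids:
        for (pid, gid), grp in clean.groupby(["participant_id", "gesture_id"], sort=True):
            grp = grp.sort_values("t", kind="stable")
            dup = grp.duplicated(subset=["t", "phase"], keep="first")
            if dup.any():
                warnings.warn(
                    f"gesture {gid!r}: {int(dup.sum())} duplicate (t, phase) events dropped",
                    stacklevel=2,
                )
                grp = grp.loc[~dup]
            t = grp["t"].to_numpy(float)
            phase = grp["phase"].to_numpy(int)
            swipe = RawSwipe(
                participant_id=str(pid),
                gesture_id=str(gid),
                t=t,
                x=grp["x"].to_numpy(float),
                y=grp["y"].to_numpy(float),
                phase=phase,
                validity=_structural_validity(phase, len(t)),
            )
            swipes.append(swipe)
    else:
        swipes = _reconstruct_gestures(clean)

    if flag_overlaps:
        swipes = flag_multiple_touch(swipes)
    return ParseResult(swipes=swipes, rejects=pd.DataFrame(rejects, columns=["row", "reason"]))


def _reconstruct_gestures(clean: pd.DataFrame) -> list[RawSwipe]:
    """Rebuild gestures from phase structure when the log has no gesture ids.

    Interleaved began events without closure mark simultaneous touches; both
    the interrupted and interrupting gesture are flagged multiple_touch.
    """
    swipes: list[RawSwipe] = []
    for pid, grp in clean.groupby("participant_id", sort=True):
        grp = grp.sort_values("t", kind="stable")
        open_rows: list[tuple[float, float, float, int]] | None = None
        counter = 0
        interleaved = False

        def close(rows, validity=None):
            nonlocal counter
            counter += 1
            arr = np.array(rows, dtype=float)
            phase = arr[:, 3].astype(int)
            v = validity or _structural_validity(phase, len(rows))
            swipes.append(
                RawSwipe(
                    participant_id=str(pid),
                    gesture_id=f"{pid}-r{counter}",
                    t=arr[:, 0],
                    x=arr[:, 1],
                    y=arr[:, 2],
                    phase=phase,
                    validity=v,
                )
            )

        for row in grp.itertuples(index=False):
            item = (row.t, row.x, row.y, int(row.phase))
            if int(row.phase) == Phase.BEGAN:
                if open_rows is not None:
                    close(open_rows, SwipeValidity.MULTIPLE_TOUCH)
                    interleaved = True
                open_rows = [item]
            elif open_rows is not None:
                open_rows.append(item)
                if int(row.phase) == Phase.ENDED:
                    close(open_rows,
                          SwipeValidity.MULTIPLE_TOUCH if interleaved else None)
                    open_rows = None
                    interleaved = False
            else:
                # moved/ended with no open gesture: orphan fragment
                close([item], SwipeValidity.MISSING_STRUCTURE)
        if open_rows is not None:
            close(open_rows, SwipeValidity.MULTIPLE_TOUCH if interleaved
                  else SwipeValidity.MISSING_STRUCTURE)
    return swipes


def flag_multiple_touch(swipes: Sequence[RawSwipe]) -> list[RawSwipe]:
    """Flag gestures whose time interval strictly overlaps another gesture
    of the same participant.

    Two gestures sharing exactly one boundary instant (one ends at t, the
    next begins at t) are rapid sequential taps, not simultaneous touches,
    and are not flagged.  The relation is symmetric: both members of an
    overlapping pair are flagged.
    """
    by_pid: dict[str, list[RawSwipe]] = {}
    for s in swipes:
        by_pid.setdefault(s.participant_id, []).append(s)
    for group in by_pid.values():
        group.sort(key=lambda s: (s.t_begin, s.t_end))
        for i, a in enumerate(group):
            for b in group[i + 1:]:
                if b.t_begin >= a.t_end:
                    break  # sorted by start: no later swipe can overlap a
                a.validity = SwipeValidity.MULTIPLE_TOUCH
                b.validity = SwipeValidity.MULTIPLE_TOUCH
    return list(swipes)


def classify_goal_directed(swipe: RawSwipe, layout: GameLayout) -> bool:
    """True iff the swipe starts inside the food area and ends inside a
    plate region (a food-to-plate swipe).

    Only the first and last recorded positions matter; the path in between
    does not affect classification.
    """
    if swipe.validity is SwipeValidity.MISSING_STRUCTURE:
        raise ValueError(
            "cannot classify a structurally invalid swipe "
            f"({swipe.gesture_id}: missing began/ended events)"
        )
    return layout.in_food_area(float(swipe.x[0]), float(swipe.y[0])) and \
        layout.in_end_area(float(swipe.x[-1]), float(swipe.y[-1]))
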