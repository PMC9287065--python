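"""End-to-end plumbing: touch events -> swipe-level kinematics table."""

from __future__ import annotations

import numpy as np
import pandas as pd

from swipekin import preprocess
from swipekin.kinematics import SwipeKinematics, compute_features, path_length
from swipekin.preprocess import regularise_sampling, velocity_profile
from swipekin.segmentation import SegmentationParams, segment_units
from swipekin.touch_io import (
    GameLayout,
    RawSwipe,
    SwipeValidity,
    classify_goal_directed,
)

__all__ = ["process_swipe", "extract_kinematics"]


def process_swipe(
    swipe: RawSwipe,
    fs: float = preprocess.DEFAULT_FS,
    ppi: float = preprocess.DEFAULT_PPI,
    fc: float = preprocess.DEFAULT_CUTOFF_HZ,
    order: int = preprocess.DEFAULT_FILTER_ORDER,
    seg_params: SegmentationParams | None = None,
) -> SwipeKinematics:
    """Run one structurally valid swipe through the full kinematic chain:
    resampling, unit conversion, smoothing, differentiation, movement-unit
    segmentation and feature extraction."""
    traj = regularise_sampling(swipe, fs=fs, ppi=ppi)
    raw_start = (float(preprocess.px_to_mm(swipe.x[0], ppi)),
                 float(preprocess.px_to_mm(swipe.y[0], ppi)))
    raw_end = (float(preprocess.px_to_mm(swipe.x[-1], ppi)),
               float(preprocess.px_to_mm(swipe.y[-1], ppi)))
    smoothed, vel = velocity_profile(traj, fs=fs, fc=fc, order=order)
    units = segment_units(vel.speed, seg_params)
    return compute_features(smoothed, vel, units, raw_start=raw_start, raw_end=raw_end)


def _stub_row(swipe: RawSwipe, ppi: float) -> dict:
    """Minimal record for swipes that cannot be processed kinematically
    (multiple touch / too few samples) but must be counted in the cascade."""
    x_mm = preprocess.px_to_mm(swipe.x, ppi)
    y_mm = preprocess.px_to_mm(swipe.y, ppi)
    target = float(np.hypot(x_mm[-1] - x_mm[0], y_mm[-1] - y_mm[0]))
    plen = path_length(x_mm, y_mm) if swipe.n_samples > 1 else 0.0
    return {
        "participant_id": swipe.participant_id,
        "gesture_id": swipe.gesture_id,
        "MT": swipe.t_end - swipe.t_begin,
        "target_distance": target,
        "straightness": plen / target if target > 0 else np.nan,
    }


def extract_kinematics(
    swipes: list[RawSwipe],
    layout: GameLayout,
    participants: pd.DataFrame | None = None,
    ppi: float = preprocess.DEFAULT_PPI,
    seg_params: SegmentationParams | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Build the food-to-plate kinematics table and per-participant totals.

    Structurally invalid gestures (missing began/ended events) cannot be
    classified and are dropped from the table; they still count towards
    each participant's total gesture count.  Multiple-touch and
    too-few-sample food-to-plate swipes appear as rows with their validity
    flag and endpoint-derived fields only, so the exclusion cascade can
    attribute them.

    Returns ``(kin, totals)``: one row per food-to-plate swipe, and one
    row per participant with ``total_swipes`` and ``goal_swipes`` counts
    (the inputs to the engagement rule).  If ``participants`` (columns
    ``participant_id``, ``group``, ``age_months``, optionally ``sex``) is
    given, its columns are merged onto the swipe table.
    """
    rows: list[dict] = []
    totals: dict[str, dict[str, int]] = {}
    for swipe in swipes:
        tot = totals.setdefault(swipe.participant_id, {"total_swipes": 0, "goal_swipes": 0})
        tot["total_swipes"] += 1
        if swipe.validity is SwipeValidity.MISSING_STRUCTURE:
            continue
        if not classify_goal_directed(swipe, layout):
            continue
        tot["goal_swipes"] += 1
        if swipe.validity is SwipeValidity.VALID:
            kin = process_swipe(swipe, ppi=ppi, seg_params=seg_params)
            row = kin.__dict__.copy()
        else:
            row = _stub_row(swipe, ppi)
        row["validity"] = swipe.validity.value
        row["n_samples"] = swipe.n_samples
        rows.append(row)

    kin_df = pd.DataFrame(rows)
    totals_df = pd.DataFrame.from_dict(totals, orient="index")
    totals_df.index.name = "participant_id"
    if participants is not None and not kin_df.empty:
        kin_df = kin_df.merge(
            participants, on="participant_id", how="left", validate="many_to_one"
        )
    return kin_df, totals_df
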