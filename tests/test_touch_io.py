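import numpy as np
import pandas as pd
import pytest

from swipekin import (
    Rect,
    SwipeValidity,
    classify_goal_directed,
    default_layout,
    flag_multiple_touch,
    parse_touch_log,
)
from swipekin.touch_io import RawSwipe

from conftest import make_events


def _swipe(pid, gid, t0, t1, n=6):
    t = np.linspace(t0, t1, n)
    phase = np.array([0] + [1] * (n - 2) + [3])
    return RawSwipe(pid, gid, t, np.zeros(n), np.zeros(n), phase)


class TestParse:
    def test_well_formed_single_gesture(self):
        ev = make_events([("g1", 0.0, 11 / 60, 12, 900, 700, 400, 760)])
        res = parse_touch_log(ev)
        assert len(res.swipes) == 1
        s = res.swipes[0]
        assert s.n_samples == 12
        assert s.validity is SwipeValidity.VALID
        assert res.rejects.empty

    def test_missing_end_structure(self):
        ev = make_events([("g1", 0.0, 0.2, 8, 900, 700, 400, 760)])
        ev = ev.iloc[:-1]  # drop the ended event
        res = parse_touch_log(ev)
        assert res.swipes[0].validity is SwipeValidity.MISSING_STRUCTURE

    def test_too_few_samples(self):
        ev = make_events([("g1", 0.0, 0.05, 4, 900, 700, 910, 700)])
        res = parse_touch_log(ev)
        assert res.swipes[0].validity is SwipeValidity.TOO_FEW_SAMPLES

    def test_overlapping_gestures_both_flagged(self):
        ev = make_events([
            ("A", 0.0, 0.5, 8, 900, 700, 400, 760),
            ("B", 0.3, 0.8, 8, 1000, 800, 1600, 760),
        ])
        res = parse_touch_log(ev)
        assert all(s.validity is SwipeValidity.MULTIPLE_TOUCH for s in res.swipes)

    def test_malformed_row_rejected_with_diagnostic(self):
        ev = make_events([("g1", 0.0, 0.2, 6, 900, 700, 400, 760)])
        ev["t"] = ev["t"].astype(object)
        ev.loc[2, "t"] = "oops"
        res = parse_touch_log(ev)
        assert len(res.rejects) == 1
        assert "malformed" in res.rejects.iloc[0]["reason"]
        # remaining events still form the gesture
        assert res.swipes[0].n_samples == 5

    def test_duplicate_event_kept_first_with_warning(self):
        ev = make_events([("g1", 0.0, 0.2, 6, 900, 700, 400, 760)])
        dup = ev.iloc[[2]].copy()
        dup["x"] = 999.0
        ev = pd.concat([ev, dup]).sort_values("t", kind="stable")
        with pytest.warns(UserWarning, match="duplicate"):
            res = parse_touch_log(ev)
        s = res.swipes[0]
        assert s.n_samples == 6
        assert 999.0 not in s.x

    def test_partition_every_row_accounted(self, rng):
        gestures = [(f"g{k}", k * 0.5, k * 0.5 + 0.3, int(rng.integers(3, 9)),
                     900, 700, 400, 760) for k in range(6)]
        ev = make_events(gestures)
        ev["x"] = ev["x"].astype(object)
        ev.loc[5, "x"] = "bad"
        res = parse_touch_log(ev)
        n_in_swipes = sum(s.n_samples for s in res.swipes)
        assert n_in_swipes + len(res.rejects) == len(ev)

    def test_gesture_reconstruction_without_ids(self):
        ev = make_events([
            ("a", 0.0, 0.2, 6, 900, 700, 400, 760),
            ("b", 0.3, 0.5, 6, 900, 700, 400, 760),
        ]).drop(columns=["gesture_id"])
        res = parse_touch_log(ev)
        assert len(res.swipes) == 2
        assert all(s.validity is SwipeValidity.VALID for s in res.swipes)

    def test_interleaved_began_without_closure_is_multiple_touch(self):
        ev = make_events([("a", 0.0, 0.4, 6, 900, 700, 400, 760)])
        ev = ev.drop(columns=["gesture_id"])
        # inject a began event mid-gesture
        extra = pd.DataFrame(
            [["P1", 0.2001, 1000.0, 800.0, 0]],
            columns=["participant_id", "t", "x", "y", "phase"],
        )
        ev = pd.concat([ev, extra]).sort_values("t", kind="stable")
        res = parse_touch_log(ev)
        assert any(s.validity is SwipeValidity.MULTIPLE_TOUCH for s in res.swipes)


class TestMultipleTouch:
    def test_disjoint_gestures_stay_valid(self):
        swipes = [_swipe("P", "a", 0.0, 0.5), _swipe("P", "b", 0.6, 1.0)]
        out = flag_multiple_touch(swipes)
        assert all(s.validity is SwipeValidity.VALID for s in out)

    def test_shared_endpoint_not_flagged(self):
        swipes = [_swipe("P", "a", 0.0, 0.5), _swipe("P", "b", 0.5, 1.0)]
        out = flag_multiple_touch(swipes)
        assert all(s.validity is SwipeValidity.VALID for s in out)

    def test_two_of_three_flagged(self):
        swipes = [
            _swipe("P", "a", 0.0, 0.5),
            _swipe("P", "b", 0.4, 0.9),
            _swipe("P", "c", 1.0, 1.4),
        ]
        out = flag_multiple_touch(swipes)
        flags = {s.gesture_id: s.validity for s in out}
        assert flags["a"] is SwipeValidity.MULTIPLE_TOUCH
        assert flags["b"] is SwipeValidity.MULTIPLE_TOUCH
        assert flags["c"] is SwipeValidity.VALID

    def test_different_participants_never_interact(self):
        swipes = [_swipe("P", "a", 0.0, 0.5), _swipe("Q", "b", 0.2, 0.7)]
        out = flag_multiple_touch(swipes)
        assert all(s.validity is SwipeValidity.VALID for s in out)

    def test_matches_pairwise_overlap_oracle(self, rng):
        """Symmetry + correctness against brute-force interval overlap."""
        for _ in range(50):
            k = int(rng.integers(2, 8))
            starts = rng.uniform(0, 5, k)
            swipes = [_swipe("P", f"g{j}", s, s + rng.uniform(0.05, 1.0))
                      for j, s in enumerate(starts)]
            ivs = [(s.t_begin, s.t_end) for s in swipes]
            expect = set()
            for i in range(k):
                for j in range(i + 1, k):
                    if ivs[i][0] < ivs[j][1] and ivs[j][0] < ivs[i][1]:
                        expect |= {i, j}
            out = flag_multiple_touch(swipes)
            got = {j for j, s in enumerate(out)
                   if s.validity is SwipeValidity.MULTIPLE_TOUCH}
            assert got == expect


class TestClassify:
    def test_food_to_plate_true(self, layout):
        s = _swipe("P", "g", 0.0, 0.5)
        s.x = np.linspace(1024, 411, 6)  # food centre -> left plate centre
        s.y = np.full(6, 768.0)
        assert classify_goal_directed(s, layout)

    def test_food_to_food_false(self, layout):
        s = _swipe("P", "g", 0.0, 0.5)
        s.x = np.linspace(1024, 900, 6)
        s.y = np.full(6, 768.0)
        assert not classify_goal_directed(s, layout)

    def test_one_pixel_outside_food_boundary(self, layout):
        s = _swipe("P", "g", 0.0, 0.5)
        fa = layout.food_area
        s.x = np.linspace(fa.x0 - 1, 411, 6)  # 1 px left of food area
        s.y = np.full(6, 768.0)
        assert not classify_goal_directed(s, layout)
        # exactly on the left edge is inside (half-open convention)
        s.x = np.linspace(fa.x0, 411, 6)
        assert classify_goal_directed(s, layout)

    def test_only_endpoints_matter(self, layout):
        s = _swipe("P", "g", 0.0, 0.5)
        s.x = np.array([1024.0, 5.0, 2000.0, 5.0, 2000.0, 411.0])
        s.y = np.array([768.0, 5.0, 1500.0, 5.0, 1500.0, 768.0])
        assert classify_goal_directed(s, layout)

    def test_missing_structure_rejected(self, layout):
        s = _swipe("P", "g", 0.0, 0.5)
        s.validity = SwipeValidity.MISSING_STRUCTURE
        with pytest.raises(ValueError):
            classify_goal_directed(s, layout)


def test_half_open_rect_membership():
    r = Rect(0, 0, 10, 10)
    assert r.contains(0, 0)
    assert not r.contains(10, 5)
    assert not r.contains(5, 10)
    assert r.contains(9.999, 9.999)
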