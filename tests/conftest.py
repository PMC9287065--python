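import numpy as np
import pandas as pd
import pytest

from swipekin import simulate


def make_events(gestures, participant="P1"):
    """Build an event-log DataFrame from (gesture_id, t0, t1, n, x0, y0, x1, y1)
    tuples; phases are began/moved/ended, positions linear."""
    rows = []
    for gid, t0, t1, n, x0, y0, x1, y1 in gestures:
        t = np.linspace(t0, t1, n)
        x = np.linspace(x0, x1, n)
        y = np.linspace(y0, y1, n)
        phase = [0] + [1] * (n - 2) + [3]
        for k in range(n):
            rows.append((participant, gid, t[k], x[k], y[k], phase[k]))
    return pd.DataFrame(rows, columns=["participant_id", "gesture_id", "t", "x", "y", "phase"])


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


#: Planted per-rule violation counts for the 500-swipe exclusion fixture.
PLANTED_EXCLUSIONS = {
    "multiple_touch": 40,
    "too_few_samples": 12,
    "sub_min_distance": 25,
    "mt_outlier": 30,
    "dist_outlier": 18,
    "straightness": 35,
}


def build_exclusion_fixture(n_total=500):
    """A kinematics table with known per-rule exclusion hit counts."""
    rows = []
    k = 0

    def row(validity="valid", n_samples=20, mt=0.5, dist=40.0, straight=1.1):
        nonlocal k
        grp = "ASD" if k % 3 == 0 else "TD"
        r = {
            "participant_id": f"P{k % 17}", "gesture_id": f"g{k}",
            "validity": validity, "n_samples": n_samples, "MT": mt,
            "target_distance": dist, "straightness": straight, "group": grp,
            "pre_first_min_dist": 0.5, "post_last_min_dist": 0.5,
        }
        k += 1
        return r

    for _ in range(PLANTED_EXCLUSIONS["multiple_touch"]):
        rows.append(row(validity="multiple_touch"))
    for _ in range(PLANTED_EXCLUSIONS["too_few_samples"]):
        rows.append(row(validity="too_few_samples", n_samples=4))
    for _ in range(PLANTED_EXCLUSIONS["sub_min_distance"]):
        rows.append(row(dist=8.0))
    for _ in range(PLANTED_EXCLUSIONS["mt_outlier"]):
        rows.append(row(mt=2.1))
    for _ in range(PLANTED_EXCLUSIONS["dist_outlier"]):
        rows.append(row(dist=80.0))
    for _ in range(PLANTED_EXCLUSIONS["straightness"]):
        rows.append(row(straight=1.6))
    while len(rows) < n_total:
        rows.append(row())
    return pd.DataFrame(rows)


@pytest.fixture
def layout():
    from swipekin import default_layout

    return default_layout()


@pytest.fixture(scope="session")
def small_cohort():
    """A modest simulated cohort reused across model tests."""
    cfg = simulate.CohortSimConfig(
        n_td=20, n_asd=15, swipes_mean=30.0, swipes_sd=5.0, seed=2024,
        outcomes=("MT", "PV", "TTPV", "PV1_b", "MU_APV", "MU"),
    )
    return cfg, simulate.simulate_cohort_outcomes(cfg)
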