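"""Independent reference implementations used only by tests.

The segmentation oracle is deliberately naive: it rescans the profile for
extrema from scratch on every pass with plain Python loops and applies the
retention criteria exhaustively, sharing no code or data structures with
the package implementation.
"""

import numpy as np


def _extrema_scan(s):
    """Alternating (index, kind) list by pairwise comparison with plateau
    collapse to midpoints."""
    # compress plateaus
    idx = [0]
    for i in range(1, len(s)):
        if s[i] != s[idx[-1]]:
            idx.append(i)
    # midpoint index of each run
    runs = []
    for k, start in enumerate(idx):
        end = idx[k + 1] - 1 if k + 1 < len(idx) else len(s) - 1
        runs.append(((start + end) // 2, s[start]))
    ext = []
    for k in range(1, len(runs) - 1):
        i, v = runs[k]
        if v > runs[k - 1][1] and v > runs[k + 1][1]:
            ext.append((i, "max"))
        elif v < runs[k - 1][1] and v < runs[k + 1][1]:
            ext.append((i, "min"))
    if ext and ext[0][1] == "max":
        ext.insert(0, (0, "min"))
    if ext and ext[-1][1] == "max":
        ext.append((len(s) - 1, "min"))
    return ext


def brute_force_segment(speed, min_change=8.0, frac=0.05):
    """Reference movement-unit segmentation.

    Returns a list of (start, peak, end) index triples under the same
    published criteria: summed rise+fall >= min_change and peak > frac of
    the global maximum; the weakest failing peak is merged into its larger
    neighbour (higher shared minimum deleted) until stable.
    """
    s = [float(v) for v in np.asarray(speed)]
    pv = max(s)
    ext = _extrema_scan(s)
    mins = [i for i, k in ext if k == "min"]
    peaks = [i for i, k in ext if k == "max"]
    if not peaks:
        return [(0, int(np.argmax(s)), len(s) - 1)]

    while len(peaks) > 1:
        failing = []
        for j, p in enumerate(peaks):
            rise = s[p] - s[mins[j]]
            fall = s[p] - s[mins[j + 1]]
            if not (rise + fall >= min_change and s[p] > frac * pv):
                failing.append((rise + fall, j))
        if not failing:
            break
        _, j = min(failing)
        if j == 0:
            drop = 1
        elif j == len(peaks) - 1:
            drop = j
        else:
            drop = j if s[mins[j]] > s[mins[j + 1]] else j + 1
        a, b = peaks[drop - 1], peaks[drop]
        peaks[drop - 1:drop + 1] = [a if s[a] >= s[b] else b]
        del mins[drop]
    return [(mins[j], peaks[j], mins[j + 1]) for j in range(len(peaks))]


def random_multibell_profile(rng, max_bells=5, n_min=60, n_max=300):
    """A seeded random speed profile built from Gaussian bumps of mixed
    amplitude (some below the retention thresholds) on a non-negative
    baseline."""
    n = int(rng.integers(n_min, n_max + 1))
    t = np.linspace(0, 1, n)
    k = int(rng.integers(1, max_bells + 1))
    s = np.zeros(n)
    for _ in range(k):
        amp = rng.choice([rng.uniform(1, 6), rng.uniform(10, 200)])
        c = rng.uniform(0.05, 0.95)
        w = rng.uniform(0.02, 0.15)
        s += amp * np.exp(-0.5 * ((t - c) / w) ** 2)
    return s
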