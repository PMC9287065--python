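"""Synthetic data with known ground truth.

Two generators mirror the two levels of the analysis:

* :func:`simulate_trajectory` emits a raw 60-Hz touch-event log (device
  pixels, began/moved/ended phases) for a swipe composed of one to five
  possibly overlapping minimum-jerk submovements plus Gaussian positional
  noise, together with the generative ground truth (true movement time,
  submovement count, analytic peak speed).  It exercises the full
  parsing-to-kinematics chain.

* :func:`simulate_cohort_outcomes` draws swipe-level outcome tables from
  the generative mixed-model family: per-subject correlated (intercept,
  Dist slope) random effects, log-normal MT/PV/TTPV, Bernoulli PV1-b,
  Poisson MU-APV and zero-truncated Poisson MU, with fixed effects and
  variance components defaulting to the study's reported estimates.  It
  exercises the model-fitting stack and drives parameter-recovery studies.

All generators are pure functions of (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import special, stats

from swipekin.touch_io import GameLayout, Phase, default_layout
from swipekin.preprocess import MM_PER_INCH

__all__ = [
    "Submovement",
    "TrajectorySimConfig",
    "GenerativeParams",
    "CohortSimConfig",
    "minimum_jerk_position",
    "minimum_jerk_velocity",
    "simulate_trajectory",
    "goal_directed_config",
    "simulate_cohort_outcomes",
    "parameter_recovery_study",
    "default_generative_params",
]

SCREEN_W_PX = 2048
SCREEN_H_PX = 1536


def minimum_jerk_position(tau: np.ndarray) -> np.ndarray:
    """Normalised minimum-jerk displacement, 0 at tau=0 to 1 at tau=1."""
    tau = np.clip(tau, 0.0, 1.0)
    return 10 * tau ** 3 - 15 * tau ** 4 + 6 * tau ** 5


def minimum_jerk_velocity(tau: np.ndarray) -> np.ndarray:
    """Normalised minimum-jerk speed (per unit of normalised time).

    The peak value is 30/16 = 1.875 at tau = 1/2, so a stroke of
    amplitude A and duration T peaks at 1.875 * A / T.
    """
    tau = np.asarray(tau, float)
    inside = (tau >= 0) & (tau <= 1)
    t = np.clip(tau, 0.0, 1.0)
    return np.where(inside, 30 * t ** 2 - 60 * t ** 3 + 30 * t ** 4, 0.0)


@dataclass(frozen=True)
class Submovement:
    """One minimum-jerk pulse: amplitude (mm), onset (s), duration (s),
    unit direction vector in screen coordinates."""

    amplitude: float
    onset: float
    duration: float
    direction: tuple[float, float] = (1.0, 0.0)

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("submovement duration must be positive")
        norm = float(np.hypot(*self.direction))
        if not np.isclose(norm, 1.0, atol=1e-6):
            object.__setattr__(self, "direction",
                               (self.direction[0] / norm, self.direction[1] / norm))


@dataclass(frozen=True)
class TrajectorySimConfig:
    submovements: tuple[Submovement, ...]
    noise_sd: float = 0.3           # mm; positional noise of the touch sensor
    fs: float = 60.0
    ppi: float = 326.0
    start_px: tuple[float, float] | None = None
    layout: GameLayout = field(default_factory=default_layout)
    participant_id: str = "sim"
    gesture_id: str = "g1"
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.submovements:
            raise ValueError("need at least one submovement")
        onsets = [s.onset for s in self.submovements]
        if any(b < a for a, b in zip(onsets, onsets[1:])):
            raise ValueError("submovement onsets must be non-decreasing")
        if self.noise_sd < 0:
            raise ValueError("noise SD must be non-negative")


def _mm_per_px(ppi: float) -> float:
    return MM_PER_INCH / ppi


def simulate_trajectory(config: TrajectorySimConfig) -> tuple[pd.DataFrame, dict]:
    """Emit a touch-event log for one simulated swipe.

    Submovement velocities sum (overlapping pulses superpose in velocity
    space); positions are the integrated path from the start point, noised
    and converted to device pixels.  Events are sampled at ``fs`` with
    phases began / moved / ended.  Raises if the noiseless path leaves the
    screen.  Ground truth reports both the generative submovement count
    and the analytic speed profile's peak (which overlapping pulses can
    merge below the submovement count).
    """
    rng = np.random.default_rng(config.seed)
    mmpp = _mm_per_px(config.ppi)
    if config.start_px is None:
        fa = config.layout.food_area
        start_px = ((fa.x0 + fa.x1) / 2.0, (fa.y0 + fa.y1) / 2.0)
    else:
        start_px = config.start_px
    start_mm = np.array(start_px) * mmpp

    total = max(s.onset + s.duration for s in config.submovements)
    dt = 1.0 / config.fs
    n = int(round(total / dt)) + 1
    t = np.arange(n) * dt

    pos = np.tile(start_mm, (n, 1))
    fine = np.linspace(0.0, total, max(20 * n, 200))
    speed_fine = np.zeros_like(fine)
    for sm in config.submovements:
        tau = (t - sm.onset) / sm.duration
        disp = sm.amplitude * minimum_jerk_position(tau)
        pos += np.outer(disp, sm.direction)
        tau_f = (fine - sm.onset) / sm.duration
        v = (sm.amplitude / sm.duration) * minimum_jerk_velocity(tau_f)
        speed_fine += v  # collinear superposition bound; exact for shared direction

    px = pos / mmpp
    if (px[:, 0].min() < 0 or px[:, 0].max() >= SCREEN_W_PX
            or px[:, 1].min() < 0 or px[:, 1].max() >= SCREEN_H_PX):
        raise ValueError("simulated trajectory leaves the screen bounds")
    noisy = px + rng.normal(0.0, config.noise_sd / mmpp, size=px.shape)

    phase = np.full(n, int(Phase.MOVED))
    phase[0] = int(Phase.BEGAN)
    phase[-1] = int(Phase.ENDED)
    events = pd.DataFrame(
        {
            "participant_id": config.participant_id,
            "gesture_id": config.gesture_id,
            "t": t,
            "x": noisy[:, 0],
            "y": noisy[:, 1],
            "phase": phase,
        }
    )
    end_mm = pos[-1]
    truth = {
        "MT": float(total),
        "n_submovements": len(config.submovements),
        "PV": float(speed_fine.max()),
        "PV1_b": bool(np.argmax(speed_fine) <= np.searchsorted(
            fine, config.submovements[0].onset + config.submovements[0].duration)),
        "target_distance": float(np.hypot(*(end_mm - start_mm))),
        "start_px": start_px,
        "end_px": tuple(px[-1]),
    }
    return events, truth


def goal_directed_config(
    distance_mm: float = 40.0,
    duration_s: float = 0.5,
    n_submovements: int = 1,
    gap_s: float = 0.15,
    noise_sd: float = 0.3,
    seed: int = 0,
    participant_id: str = "sim",
    gesture_id: str = "g1",
) -> TrajectorySimConfig:
    """Convenience config: a leftward food-to-plate swipe.

    The movement starts at the food-area centre and heads toward the left
    plate; ``n_submovements`` splits the amplitude into equal pulses
    separated by ``gap_s`` of rest (well-separated, so each should be
    recovered as one movement unit)."""
    layout = default_layout()
    amp = distance_mm / n_submovements
    subs = tuple(
        Submovement(amp, onset=k * (duration_s + gap_s), duration=duration_s,
                    direction=(-1.0, 0.0))
        for k in range(n_submovements)
    )
    return TrajectorySimConfig(
        submovements=subs, noise_sd=noise_sd, layout=layout, seed=seed,
        participant_id=participant_id, gesture_id=gesture_id,
    )


# --------------------------------------------------------------------------
# Cohort-level outcome simulation
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class GenerativeParams:
    """Generative mixed-model parameters for one outcome (link scale)."""

    family: str                      # gaussian | binomial | poisson | ztpoisson
    transform: str                   # identity | log (gaussian only)
    fixed: dict[str, float]          # term -> coefficient on the link scale
    tau00: float
    tau11: float
    rho01: float
    sigma2: float = float("nan")     # residual variance (gaussian only)

    def cov(self) -> np.ndarray:
        off = self.rho01 * np.sqrt(self.tau00 * self.tau11)
        c = np.array([[self.tau00, off], [off, self.tau11]])
        if np.any(np.linalg.eigvalsh(c) < -1e-10):
            raise ValueError("random-effect covariance not positive semi-definite")
        return c


def default_generative_params() -> dict[str, GenerativeParams]:
    """Reported fixed effects (log of the exponentiated coefficients) and
    variance components for the five primary outcomes; the secondary
    outcomes (MU, PV1, %Dec) use plausible values of the same magnitude,
    since no published estimates pin them down."""
    ln = np.log
    return {
        "MT": GenerativeParams(
            "gaussian", "log",
            {"Intercept": ln(0.70), "Dist": ln(1.10), "age": ln(0.71),
             "ASD": ln(1.13), "ASD:age": ln(1.33)},
            tau00=0.13, tau11=0.00, rho01=-0.48, sigma2=0.08),
        "PV": GenerativeParams(
            "gaussian", "log",
            {"Intercept": ln(114.11), "Dist": ln(1.17), "age": ln(1.25),
             "ASD": ln(0.92), "ASD:age": ln(0.88)},
            tau00=0.06, tau11=0.00, rho01=-0.32, sigma2=0.09),
        "TTPV": GenerativeParams(
            "gaussian", "log",
            {"Intercept": ln(0.28), "Dist": ln(1.13), "age": ln(0.74),
             "ASD": ln(1.20), "ASD:age": ln(1.21)},
            tau00=0.14, tau11=0.00, rho01=-0.11, sigma2=0.21),
        "PV1_b": GenerativeParams(
            "binomial", "identity",
            {"Intercept": ln(4.45), "Dist": ln(0.75), "age": ln(1.89),
             "ASD": ln(0.56)},
            tau00=0.62, tau11=0.03, rho01=-0.52),
        "MU_APV": GenerativeParams(
            "poisson", "identity",
            {"Intercept": ln(0.29), "Dist": ln(1.33), "age": ln(0.61),
             "ASD": ln(1.36), "ASD:age": ln(1.35), "ASD:Dist": ln(0.91)},
            tau00=0.30, tau11=0.01, rho01=-0.86),
        "MU": GenerativeParams(
            "ztpoisson", "identity",
            {"Intercept": ln(1.8), "Dist": ln(1.20), "age": ln(0.85),
             "ASD": ln(1.15)},
            tau00=0.10, tau11=0.005, rho01=-0.40),
        "PV1": GenerativeParams(
            "gaussian", "identity",
            {"Intercept": 100.0, "Dist": 10.0, "age": 15.0, "ASD": -8.0},
            tau00=250.0, tau11=4.0, rho01=-0.30, sigma2=900.0),
        "pct_dec": GenerativeParams(
            "gaussian", "identity",
            {"Intercept": 50.0, "Dist": 1.0, "age": -1.0, "ASD": 2.0},
            tau00=25.0, tau11=0.5, rho01=-0.20, sigma2=150.0),
    }


#: Pooled distance-category proportions observed in gameplay.
DEFAULT_DIST_PROBS = (0.059, 0.307, 0.189, 0.217, 0.164, 0.064)


@dataclass(frozen=True)
class CohortSimConfig:
    n_td: int = 43
    n_asd: int = 28
    swipes_mean: float = 66.0
    swipes_sd: float = 27.0
    swipes_min: int = 5
    age_range: tuple[float, float] = (2.8, 6.6)
    age_mean: float = 4.7
    age_sd: float = 0.905
    dist_probs: tuple[float, ...] = DEFAULT_DIST_PROBS
    params: dict[str, GenerativeParams] = field(default_factory=default_generative_params)
    outcomes: tuple[str, ...] | None = None   # subset to simulate; None = all
    seed: int = 0


def _draw_ages(rng: np.random.Generator, n: int, cfg: CohortSimConfig) -> np.ndarray:
    lo, hi = cfg.age_range
    a = (lo - cfg.age_mean) / cfg.age_sd
    b = (hi - cfg.age_mean) / cfg.age_sd
    return stats.truncnorm.rvs(a, b, loc=cfg.age_mean, scale=cfg.age_sd,
                               size=n, random_state=rng)


def _eta(beta: dict[str, float], frame: pd.DataFrame) -> np.ndarray:
    eta = np.full(len(frame), beta.get("Intercept", 0.0))
    d, a, g = (frame[c].to_numpy(float) for c in ("dist_c", "age_c", "asd"))
    eta += beta.get("Dist", 0.0) * d + beta.get("age", 0.0) * a + beta.get("ASD", 0.0) * g
    eta += beta.get("ASD:age", 0.0) * g * a + beta.get("ASD:Dist", 0.0) * g * d
    eta += beta.get("Dist:age", 0.0) * d * a
    return eta


def _sample_ztpoisson(rng: np.random.Generator, mu: np.ndarray) -> np.ndarray:
    """Poisson conditioned on >= 1 via inverse-CDF restriction."""
    p0 = stats.poisson.cdf(0, mu)
    u = rng.uniform(size=len(mu))
    return stats.poisson.ppf(p0 + u * (1.0 - p0), mu).astype(int)


def simulate_cohort_outcomes(config: CohortSimConfig | None = None,
                             seed: int | None = None) -> pd.DataFrame:
    """Draw a swipe-level outcome table from the generative model.

    Returns a modelling-ready frame: participant_id, group, asd, age
    (months, years, centred), distance category and centred index, and one
    column per simulated outcome (plus log transforms for the log-normal
    outcomes).  Random effects are drawn independently per outcome, each
    from the bivariate normal implied by (tau00, tau11, rho01).
    """
    cfg = config or CohortSimConfig()
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    n_sub = cfg.n_td + cfg.n_asd
    groups = np.array(["TD"] * cfg.n_td + ["ASD"] * cfg.n_asd)
    ages = _draw_ages(rng, n_sub, cfg)
    n_swipes = np.maximum(
        cfg.swipes_min,
        np.round(rng.normal(cfg.swipes_mean, cfg.swipes_sd, n_sub)).astype(int),
    )

    rows = []
    for i in range(n_sub):
        cats = rng.choice(np.arange(1, 7), size=n_swipes[i], p=cfg.dist_probs)
        for c in cats:
            rows.append((f"S{i:03d}", groups[i], ages[i], int(c)))
    frame = pd.DataFrame(rows, columns=["participant_id", "group", "age_years", "dist_cat"])
    frame["age_months"] = frame["age_years"] * 12.0
    frame["age_c"] = frame["age_years"] - 4.7
    frame["asd"] = (frame["group"] == "ASD").astype(int)
    frame["dist_c"] = frame["dist_cat"] - 3
    codes = frame["participant_id"].map(
        {f"S{i:03d}": i for i in range(n_sub)}).to_numpy()

    outcomes = cfg.outcomes or tuple(cfg.params)
    for name in outcomes:
        gp = cfg.params[name]
        cov = gp.cov()
        b = rng.multivariate_normal(np.zeros(2), cov, size=n_sub,
                                    method="svd")  # svd tolerates tau11 = 0
        eta = _eta(gp.fixed, frame)
        eta = eta + b[codes, 0] + b[codes, 1] * frame["dist_c"].to_numpy(float)
        if gp.family == "gaussian":
            y = eta + rng.normal(0.0, np.sqrt(gp.sigma2), len(frame))
            if gp.transform == "log":
                frame[f"log_{name}"] = y
                frame[name] = np.exp(y)
            else:
                frame[name] = y
        elif gp.family == "binomial":
            frame[name] = rng.binomial(1, special.expit(eta))
        elif gp.family == "poisson":
            frame[name] = rng.poisson(np.exp(eta))
        elif gp.family == "ztpoisson":
            frame[name] = _sample_ztpoisson(rng, np.exp(eta))
        else:
            raise ValueError(f"unknown family {gp.family!r}")
    return frame


def parameter_recovery_study(
    n_replicates: int,
    config: CohortSimConfig | None = None,
    outcomes: tuple[str, ...] | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate-fit-collect recovery summary for the final models.

    For each replicate a cohort is drawn and every requested outcome's
    final model is refitted; the summary reports, per (outcome, term),
    the generative truth, mean estimate, bias, Monte-Carlo standard
    error, RMSE and 95% CI coverage.  Replicate-level fit failures are
    recorded as a failure count, not raised.
    """
    from swipekin.mixed_models import final_model_specs, fit_mixed

    if n_replicates < 2:
        raise ValueError("need at least 2 replicates")
    cfg = config or CohortSimConfig()
    outcomes = outcomes or ("MT", "PV", "TTPV", "PV1_b", "MU_APV")
    cfg = replace(cfg, outcomes=outcomes)
    specs = final_model_specs()
    seeds = np.random.SeedSequence(seed).generate_state(n_replicates) % (2 ** 31)

    est: dict[tuple[str, str], list[float]] = {}
    cover: dict[tuple[str, str], list[bool]] = {}
    fails: dict[str, int] = {o: 0 for o in outcomes}
    for r in range(n_replicates):
        frame = simulate_cohort_outcomes(cfg, seed=int(seeds[r]))
        for name in outcomes:
            spec = specs[name]
            try:
                fit = fit_mixed(frame, spec)
            except Exception:
                fails[name] += 1
                continue
            for term in spec.terms:
                key = (name, term)
                est.setdefault(key, []).append(fit.coef(term))
                lo, hi = fit.ci(term)
                truth = cfg.params[name].fixed.get(term, 0.0)
                cover.setdefault(key, []).append(lo <= truth <= hi)

    rows = []
    for (name, term), values in est.items():
        v = np.asarray(values)
        truth = cfg.params[name].fixed.get(term, 0.0)
        rows.append({
            "outcome": name,
            "term": term,
            "truth": truth,
            "mean_estimate": v.mean(),
            "bias": v.mean() - truth,
            "mc_se": v.std(ddof=1) / np.sqrt(len(v)),
            "rmse": float(np.sqrt(np.mean((v - truth) ** 2))),
            "coverage": float(np.mean(cover[(name, term)])),
            "n_fits": len(v),
            "n_failures": fails[name],
        })
    return pd.DataFrame(rows)
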