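"""Trajectory conditioning: units, resampling, smoothing, differentiation.

Pixel coordinates are converted to millimetres (326 ppi display), timestamps
are regularised onto the nominal 60-Hz grid when jitter exceeds tolerance,
positions are smoothed with a fourth-order zero-phase 8-Hz low-pass
Butterworth filter (forward-backward application), and velocities are
obtained with a fourth-order five-point-stencil derivative.  Speed is the
Euclidean norm of the x- and y-velocity components.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal

from swipekin.touch_io import RawSwipe

__all__ = [
    "MM_PER_INCH",
    "Trajectory",
    "VelocityProfile",
    "px_to_mm",
    "regularise_sampling",
    "lowpass_zero_phase",
    "derivative_five_point",
    "speed",
    "velocity_profile",
]

MM_PER_INCH = 25.4

#: Device characteristics: sampling rate and display density.
DEFAULT_FS = 60.0
DEFAULT_PPI = 326.0
DEFAULT_CUTOFF_HZ = 8.0
DEFAULT_FILTER_ORDER = 4
DEFAULT_JITTER_TOLERANCE = 0.10


@dataclass
class Trajectory:
    """Uniformly sampled 2-D finger position in millimetres."""

    participant_id: str
    gesture_id: str
    t: np.ndarray
    x: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        if len(self.t) < 5:
            raise ValueError("trajectory needs at least 5 samples")
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("trajectory timestamps must be strictly increasing")

    @property
    def dt(self) -> float:
        return float(np.mean(np.diff(self.t)))


@dataclass
class VelocityProfile:
    """Velocity components and speed, same length as the trajectory."""

    vx: np.ndarray
    vy: np.ndarray
    speed: np.ndarray


def px_to_mm(value, ppi: float = DEFAULT_PPI):
    """Convert device pixels to millimetres (linear; 326 px = 1 inch)."""
    if ppi <= 0:
        raise ValueError(f"ppi must be positive, got {ppi}")
    return np.asarray(value, dtype=float) * MM_PER_INCH / ppi


def regularise_sampling(
    swipe: RawSwipe,
    fs: float = DEFAULT_FS,
    ppi: float = DEFAULT_PPI,
    jitter_tolerance: float = DEFAULT_JITTER_TOLERANCE,
) -> Trajectory:
    """Place a swipe's positions on a uniform sampling grid, in mm.

    The device nominally samples at ``fs``; when the observed timestamp
    jitter is within ``jitter_tolerance`` of the nominal interval the
    samples pass through unchanged (no resampling artefacts).  Otherwise
    positions are linearly interpolated onto a uniform grid of
    ``round(span * fs) + 1`` points spanning [t_begin, t_end].
    """
    t = np.asarray(swipe.t, dtype=float)
    if len(t) < 5:
        raise ValueError(f"swipe {swipe.gesture_id}: fewer than 5 samples")
    dts = np.diff(t)
    if np.any(dts <= 0):
        raise ValueError(f"swipe {swipe.gesture_id}: non-monotone timestamps")
    x_mm = px_to_mm(swipe.x, ppi)
    y_mm = px_to_mm(swipe.y, ppi)
    dt = 1.0 / fs
    if np.max(np.abs(dts - dt)) <= jitter_tolerance * dt:
        return Trajectory(swipe.participant_id, swipe.gesture_id, t, x_mm, y_mm)
    span = t[-1] - t[0]
    n = int(round(span * fs)) + 1
    if n < 5:
        raise ValueError(
            f"swipe {swipe.gesture_id}: span {span:.3f}s too short for a "
            "5-point grid at the nominal rate"
        )
    grid = t[0] + np.arange(n) * dt
    grid[-1] = min(grid[-1], t[-1])  # guard against extrapolation at the tail
    return Trajectory(
        swipe.participant_id,
        swipe.gesture_id,
        grid,
        np.interp(grid, t, x_mm),
        np.interp(grid, t, y_mm),
    )


def lowpass_zero_phase(
    series: np.ndarray,
    fs: float = DEFAULT_FS,
    fc: float = DEFAULT_CUTOFF_HZ,
    order: int = DEFAULT_FILTER_ORDER,
) -> np.ndarray:
    """Zero-phase low-pass Butterworth filter (forward-backward).

    A Butterworth filter of the given order is applied forwards then
    backwards, cancelling phase lag; the effective amplitude response is
    the squared Butterworth magnitude, 1 / (1 + (f/fc)^(2*order)).  Odd
    reflection padding of length 3*order is used at the edges.  Series too
    short for the padding pass through unfiltered with a warning rather
    than being dropped: the only hard length rule upstream is the 5-sample
    minimum.
    """
    series = np.asarray(series, dtype=float)
    if fc >= fs / 2:
        raise ValueError(f"cutoff {fc} Hz must be below Nyquist ({fs / 2} Hz)")
    padlen = 3 * order
    if len(series) <= padlen:
        warnings.warn(
            f"series of length {len(series)} too short for zero-phase "
            f"filtering (needs > {padlen}); returning unfiltered",
            stacklevel=2,
        )
        return series.copy()
    b, a = signal.butter(order, fc / (fs / 2.0))
    return signal.filtfilt(b, a, series, padtype="odd", padlen=padlen)


def butterworth_gain(f, fc: float = DEFAULT_CUTOFF_HZ, fs: float = DEFAULT_FS,
                     order: int = DEFAULT_FILTER_ORDER, zero_phase: bool = True):
    """Closed-form amplitude gain of the (optionally forward-backward)
    Butterworth filter at frequency ``f``.

    The implemented filter is the digital (bilinear-transform) Butterworth,
    whose exact squared magnitude is ``1 / (1 + (tan(pi f/fs) /
    tan(pi fc/fs))^(2 order))`` — the familiar analog form ``(f/fc)^(2
    order)`` with frequencies pre-warped; the two agree well below the
    Nyquist frequency.  With ``zero_phase`` the forward-backward pass
    squares the magnitude (and the gain at the cutoff is exactly 1/2).
    """
    warped = np.tan(np.pi * np.asarray(f, dtype=float) / fs) / np.tan(np.pi * fc / fs)
    g2 = 1.0 / (1.0 + warped ** (2 * order))
    return g2 if zero_phase else np.sqrt(g2)


def derivative_five_point(series: np.ndarray, dt: float) -> np.ndarray:
    """Fourth-order five-point-stencil derivative.

    Interior samples use (-f[i+2] + 8 f[i+1] - 8 f[i-1] + f[i-2]) / (12 dt),
    exact for polynomials up to degree four.  The two samples at each edge
    use second-order one-sided/central differences so that the derivative —
    and hence movement timing — is defined over the full touch interval.
    """
    f = np.asarray(series, dtype=float)
    n = len(f)
    if n < 5:
        raise ValueError(f"five-point stencil needs >= 5 samples, got {n}")
    if dt <= 0:
        raise ValueError(f"dt must be positive, got {dt}")
    d = np.empty(n)
    d[2:-2] = (-f[4:] + 8.0 * f[3:-1] - 8.0 * f[1:-3] + f[:-4]) / (12.0 * dt)
    d[0] = (-3.0 * f[0] + 4.0 * f[1] - f[2]) / (2.0 * dt)
    d[1] = (f[2] - f[0]) / (2.0 * dt)
    d[-2] = (f[-1] - f[-3]) / (2.0 * dt)
    d[-1] = (3.0 * f[-1] - 4.0 * f[-2] + f[-3]) / (2.0 * dt)
    return d


def speed(vx: np.ndarray, vy: np.ndarray) -> np.ndarray:
    """Speed as the Euclidean norm of the velocity components."""
    vx = np.asarray(vx, dtype=float)
    vy = np.asarray(vy, dtype=float)
    if vx.shape != vy.shape:
        raise ValueError(f"component length mismatch: {vx.shape} vs {vy.shape}")
    return np.hypot(vx, vy)


def velocity_profile(
    traj: Trajectory,
    fs: float = DEFAULT_FS,
    fc: float = DEFAULT_CUTOFF_HZ,
    order: int = DEFAULT_FILTER_ORDER,
) -> tuple[Trajectory, VelocityProfile]:
    """Filter a trajectory and differentiate it.

    Returns the smoothed trajectory (x and y filtered independently) and
    its velocity profile.  All outputs have the trajectory's length.
    """
    dt = 1.0 / fs
    xs = lowpass_zero_phase(traj.x, fs=fs, fc=fc, order=order)
    ys = lowpass_zero_phase(traj.y, fs=fs, fc=fc, order=order)
    smoothed = Trajectory(traj.participant_id, traj.gesture_id, traj.t, xs, ys)
    vx = derivative_five_point(xs, dt)
    vy = derivative_five_point(ys, dt)
    return smoothed, VelocityProfile(vx=vx, vy=vy, speed=speed(vx, vy))
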